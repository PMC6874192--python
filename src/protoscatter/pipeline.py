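"""Patient and compensator scatter factors.

The verification-plan workflow: compute the dose at the calculation point
in the patient phantom, rebuild the geometry as a homogeneous water
phantom with the point moved to the same water-equivalent depth (WED)
along the central beam axis, recompute the dose there with and without the
compensator, and form

    PSF  = d_patient,comp / d_water,comp      (patient scatter factor)
    CSF  = d_water,comp   / d_water,no-comp   (compensator scatter factor)
    CPSF = PSF * CSF

The beam (source position, air gap, fluence, SOBP weights, beamlet
lattice) is identical across the three dose calls; only the medium and,
for the third call, the compensator change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePlanError, InvalidInputError
from .materials import RspCalibration
from .phantoms import HUGrid, TargetSpec
from .compensator import CompensatorMap
from .engine import BeamSpec, Ray, SobpCurve, dose_at_point, trace_path, _sobp_for_beam

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScatterFactors:
    """PSF/CSF/CPSF triple for one field plus the underlying doses."""

    psf: float
    csf: float
    cpsf: float
    wed_cm: float
    d_patient: float
    d_verif_comp: float
    d_verif_nocomp: float

    def __post_init__(self) -> None:
        if min(self.d_patient, self.d_verif_comp, self.d_verif_nocomp) <= 0:
            raise DegeneratePlanError("all three doses must be positive")
        if self.psf <= 0 or self.csf <= 0:
            raise DegeneratePlanError("scatter factors must be positive")
        if abs(self.cpsf - self.psf * self.csf) > 1e-12 * abs(self.cpsf):
            raise InvalidInputError("cpsf must equal psf * csf")

    def to_dict(self) -> dict:
        return {
            "psf": self.psf,
            "csf": self.csf,
            "cpsf": self.cpsf,
            "wed_cm": self.wed_cm,
            "d_patient": self.d_patient,
            "d_verif_comp": self.d_verif_comp,
            "d_verif_nocomp": self.d_verif_nocomp,
        }


def build_verification_geometry(grid: HUGrid, beam: BeamSpec, point_mm,
                                cal: RspCalibration) -> tuple[HUGrid, np.ndarray]:
    """Water phantom and matched-WED point for the verification plan.

    The water grid keeps the patient grid's lateral extent, entrance plane
    (preserving the aperture-to-skin distance) and spacing; the returned
    point sits on the central axis at a geometric depth equal to the
    patient WED of ``point_mm``, matched within 0.1 mm water. If the
    patient WED exceeds the grid's depth the water grid is extended and a
    log record is emitted.
    """
    p = np.asarray(point_mm, float)
    source = p + np.array([0.0, 0.0, -beam.sad_cm * 10.0])
    axis = Ray(source, np.array([0.0, 0.0, 1.0]))
    t_plane = p[2] - source[2]
    wed_cm, _, _ = trace_path(grid, axis, cal, t_plane)

    nz_needed = int(np.ceil((wed_cm * 10.0 + 50.0) / grid.spacing[2]))
    nz = grid.shape[2]
    if nz_needed > nz:
        log.info("extending verification water grid from %d to %d slices", nz, nz_needed)
        nz = nz_needed
    water = HUGrid(
        np.zeros((grid.shape[0], grid.shape[1], nz), dtype=np.int16),
        grid.spacing,
        grid.origin,
    )
    # Water RSP from the calibration at HU 0 (1.0 for the default); solve
    # geometric depth so that depth * rsp_water = patient WED.
    rsp_water = float(cal.rsp(0))
    depth_mm = wed_cm * 10.0 / rsp_water
    point2 = np.array([p[0], p[1], grid.origin[2] + depth_mm])
    check, _, _ = trace_path(water, Ray(source, np.array([0.0, 0.0, 1.0])),
                             cal, point2[2] - source[2])
    if abs(check - wed_cm) > 0.01:  # 0.1 mm water
        raise DegeneratePlanError(
            f"verification WED {check:.3f} cm does not match patient WED {wed_cm:.3f} cm"
        )
    return water, point2


def axial_dose_gradient(grid: HUGrid, beam: BeamSpec, comp, point_mm,
                        cal: RspCalibration, step_mm: float = 1.0,
                        sobp: SobpCurve | None = None) -> float:
    """Relative axial dose gradient (fraction per mm) at the calculation
    point; large values flag a gradient-region point whose scatter factors
    are shift-sensitive."""
    p = np.asarray(point_mm, float)
    lo = dose_at_point(grid, beam, comp, p - [0, 0, step_mm], cal, p, sobp).value
    hi = dose_at_point(grid, beam, comp, p + [0, 0, step_mm], cal, p, sobp).value
    mid = dose_at_point(grid, beam, comp, p, cal, p, sobp).value
    if mid <= 0:
        raise DegeneratePlanError("zero dose at calculation point")
    return (hi - lo) / (2 * step_mm) / mid


def compute_scatter_factors(grid: HUGrid, beam: BeamSpec,
                            comp: CompensatorMap | None, target: TargetSpec,
                            cal: RspCalibration,
                            point_mm=None) -> ScatterFactors:
    """Run the verification-plan workflow for one field.

    The calculation point defaults to the target centroid (the isocentre
    surrogate); the three dose calls share the beam, SOBP weights and
    beamlet lattice exactly, so a homogeneous water patient gives PSF = 1
    and a zero-thickness compensator gives CSF = 1.
    """
    p = np.asarray(target.centroid if point_mm is None else point_mm, float)
    sobp = _sobp_for_beam(beam.range_cm, beam.modulation_cm)

    d_pat = dose_at_point(grid, beam, comp, p, cal, isocenter_mm=p, sobp=sobp)
    water, p2 = build_verification_geometry(grid, beam, p, cal)
    d_vc = dose_at_point(water, beam, comp, p2, cal, isocenter_mm=p, sobp=sobp)
    d_vn = dose_at_point(water, beam, None, p2, cal, isocenter_mm=p, sobp=sobp)

    if min(d_pat.value, d_vc.value, d_vn.value) <= 0:
        raise DegeneratePlanError(
            f"zero dose in workflow: d_p/c={d_pat.value}, "
            f"d_vp/c={d_vc.value}, d_vp/nc={d_vn.value}"
        )
    psf = d_pat.value / d_vc.value
    csf = d_vc.value / d_vn.value
    return ScatterFactors(
        psf=psf,
        csf=csf,
        cpsf=psf * csf,
        wed_cm=d_pat.wed_cm,
        d_patient=d_pat.value,
        d_verif_comp=d_vc.value,
        d_verif_nocomp=d_vn.value,
    )
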