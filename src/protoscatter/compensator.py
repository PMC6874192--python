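"""Range compensator design and shape-irregularity metrics.

A range compensator is a patient-specific PMMA block whose thickness map
conforms the beam's distal edge to the target: at each lateral position the
thickness is the water-equivalent overshoot of the prescribed range beyond
the distal target edge, divided by the compensator material's relative
stopping power.

The irregularity metric is the interquartile range (IQR) of thickness
within a circle around the central beam axis whose radius is the maximum
scattering distance of the beam — three projected Highland sigmas for the
median compensator thickness at the beam energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError
from .materials import RspCalibration
from .phantoms import HUGrid, TargetSpec
from . import engine
from .engine import (
    PMMA_RSP,
    PMMA_X0_CM,
    BeamSpec,
    bragg_kleeman_energy,
    highland_theta0,
)

#: Minimum thickness (cm) used when evaluating the Highland angle of a
#: nearly empty compensator, so the scattering radius never collapses.
MIN_SCATTER_THICKNESS_CM = 0.1


@dataclass
class CompensatorMap:
    """Lateral thickness map (cm of compensator material).

    ``thickness[i, j]`` is the thickness at lateral offset
    ``((i - (n-1)/2) * lateral_spacing + center[0],
       (j - (m-1)/2) * lateral_spacing + center[1])`` cm from the beam
    axis at the isocentre plane.
    """

    thickness: np.ndarray
    lateral_spacing_cm: float
    material_rsp: float = PMMA_RSP
    center_cm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, float)
        if self.thickness.ndim != 2 or self.thickness.size == 0:
            raise InvalidInputError("thickness map must be a non-empty 2-D array")
        if (self.thickness < 0).any():
            raise InvalidInputError("compensator thickness must be non-negative")
        if self.lateral_spacing_cm <= 0:
            raise InvalidInputError("lateral spacing must be positive")

    def cell_coords(self) -> tuple[np.ndarray, np.ndarray]:
        n, m = self.thickness.shape
        x = (np.arange(n) - (n - 1) / 2.0) * self.lateral_spacing_cm + self.center_cm[0]
        y = (np.arange(m) - (m - 1) / 2.0) * self.lateral_spacing_cm + self.center_cm[1]
        return x, y

    def thickness_at(self, x_cm, y_cm) -> np.ndarray:
        """Nearest-cell lookup at lateral offsets (cm); clamps at edges."""
        n, m = self.thickness.shape
        i = np.rint(
            (np.asarray(x_cm, float) - self.center_cm[0]) / self.lateral_spacing_cm
            + (n - 1) / 2.0
        ).astype(int)
        j = np.rint(
            (np.asarray(y_cm, float) - self.center_cm[1]) / self.lateral_spacing_cm
            + (m - 1) / 2.0
        ).astype(int)
        return self.thickness[np.clip(i, 0, n - 1), np.clip(j, 0, m - 1)]


@dataclass(frozen=True)
class IqrMetric:
    """IQR of compensator thickness within the scattering radius."""

    iqr_cm: float
    radius_cm: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.iqr_cm < 0 or self.n_samples < 4:
            raise InvalidInputError("IQR must be >= 0 from >= 4 samples")


def distal_wed_map(grid: HUGrid, beam: BeamSpec, target: TargetSpec,
                   cal: RspCalibration, lateral_spacing_cm: float | None = None):
    """Per-lateral-position WED (cm) from the surface to the deepest target
    voxel along each source ray; NaN where the ray misses the target.

    Returns ``(wed_map, spacing_cm)`` on a grid covering the aperture.
    """
    spacing = lateral_spacing_cm or beam.beamlet_spacing_cm
    iso = target.centroid
    source = iso + np.array([0.0, 0.0, -beam.sad_cm * 10.0])
    n_half = int(np.ceil(beam.field_radius_cm / spacing))
    axis = np.arange(-n_half, n_half + 1) * spacing
    wed_map = np.full((axis.size, axis.size), np.nan)
    for a, u in enumerate(axis):
        for b, v in enumerate(axis):
            q = iso + np.array([u * 10.0, v * 10.0, 0.0])
            dvec = q - source
            dvec = dvec / np.linalg.norm(dvec)
            lengths_mm, idx = engine._ray_segments(grid, source, dvec)
            if lengths_mm.size == 0:
                continue
            in_target = target.mask[idx]
            if not in_target.any():
                continue
            last = np.where(in_target)[0][-1]
            rsp = cal.rsp(grid.values[idx][: last + 1])
            wed_map[a, b] = float(np.dot(lengths_mm[: last + 1] / 10.0, rsp))
    return wed_map, spacing


def design_compensator(grid: HUGrid, beam: BeamSpec, target: TargetSpec,
                       cal: RspCalibration, lateral_spacing_cm: float | None = None,
                       material_rsp: float = PMMA_RSP) -> CompensatorMap:
    """Design a range compensator by distal-edge ray tracing.

    t(x, y) = max(0, (R - WED_to_distal_target(x, y)) / material_rsp); rays
    that miss the target take the maximum neighbouring thickness (no
    smearing margin beyond that rule). Warns if the prescribed range is
    short of the distal target everywhere (all-zero compensator).
    """
    wed_map, spacing = distal_wed_map(grid, beam, target, cal, lateral_spacing_cm)
    if np.all(np.isnan(wed_map)):
        raise InvalidInputError("no source ray intersects the target")
    t = (beam.range_cm - wed_map) / material_rsp
    t = np.where(np.isnan(wed_map), np.nan, np.maximum(t, 0.0))
    # fill rays that missed the target with the max of their neighbours
    while np.isnan(t).any():
        filled = t.copy()
        nan_idx = np.argwhere(np.isnan(t))
        progress = False
        for i, j in nan_idx:
            lo_i, hi_i = max(0, i - 1), min(t.shape[0], i + 2)
            lo_j, hi_j = max(0, j - 1), min(t.shape[1], j + 2)
            patch = t[lo_i:hi_i, lo_j:hi_j]
            if np.isnan(patch).all():
                continue
            filled[i, j] = np.nanmax(patch)
            progress = True
        t = filled
        if not progress:  # pragma: no cover - defensive
            t = np.where(np.isnan(t), 0.0, t)
    if np.all(t == 0.0):
        warnings.warn(
            "prescribed range does not exceed the distal target WED anywhere; "
            "compensator is all zero",
            stacklevel=2,
        )
    return CompensatorMap(t, spacing, material_rsp)


def scatter_radius(beam: BeamSpec, comp: CompensatorMap, depth_cm: float) -> float:
    """Maximum scattering distance (cm) at a depth: three Highland sigmas
    for the median compensator thickness, drifted over the air gap plus the
    depth.

    The Highland angle uses the beam energy whose Bragg-Kleeman range
    equals the prescribed range, and the PMMA radiation length; a 0.1 cm
    thickness floor keeps the radius finite for flat or empty maps.
    """
    if depth_cm < 0:
        raise InvalidInputError("depth must be non-negative")
    if comp.thickness.size == 0:
        raise InvalidInputError("zero-area compensator")
    med = float(np.median(comp.thickness))
    t_eff = max(med, MIN_SCATTER_THICKNESS_CM)
    energy = bragg_kleeman_energy(beam.range_cm)
    theta0 = highland_theta0(t_eff / PMMA_X0_CM, energy)
    drift = beam.air_gap_cm + depth_cm
    return 3.0 * theta0 * drift


def compensator_iqr(comp: CompensatorMap, radius_cm: float) -> IqrMetric:
    """IQR (Q3 - Q1, linear interpolation of order statistics) of the
    thickness values at lateral grid points within ``radius_cm`` of the
    central beam axis."""
    if radius_cm <= 0:
        raise InvalidInputError("radius must be positive")
    x, y = comp.cell_coords()
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    vals = comp.thickness[r2 <= radius_cm**2]
    if vals.size < 4:
        raise InsufficientDataError(
            f"only {vals.size} thickness samples within {radius_cm} cm; need >= 4"
        )
    q1, q3 = np.percentile(vals, [25, 75])
    return IqrMetric(float(q3 - q1), float(radius_cm), int(vals.size))


def make_rippled_compensator(base_cm: float, amplitude_cm: float,
                             field_radius_cm: float = 5.0,
                             spacing_cm: float = 0.2,
                             n_lobes: int = 4) -> CompensatorMap:
    """Synthetic compensator family of controllable ruggedness.

    Thickness grows quadratically toward the periphery with an azimuthal
    ripple; amplitude 0 gives a flat slab. Used to probe the IQR-to-CSF
    relationship without patient anatomy.
    """
    if base_cm < 0 or amplitude_cm < 0:
        raise InvalidInputError("base and amplitude must be non-negative")
    n_half = int(np.ceil(field_radius_cm / spacing_cm))
    axis = np.arange(-n_half, n_half + 1) * spacing_cm
    x, y = np.meshgrid(axis, axis, indexing="ij")
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    rn = np.clip(r / field_radius_cm, 0.0, 1.0)
    t = base_cm + amplitude_cm * rn**2 * (1.0 + 0.5 * np.cos(n_lobes * phi)) / 1.5
    return CompensatorMap(t, spacing_cm)


# ---------------------------------------------------------------------------
# I/O

def write_thickness_csv(comp: CompensatorMap, path) -> None:
    """Write the thickness map as CSV with header ``x_cm,y_cm,thickness_cm``."""
    x, y = comp.cell_coords()
    xx, yy = np.meshgrid(x, y, indexing="ij")
    pd.DataFrame(
        {
            "x_cm": xx.ravel(),
            "y_cm": yy.ravel(),
            "thickness_cm": comp.thickness.ravel(),
        }
    ).to_csv(path, index=False)


def read_thickness_csv(path, material_rsp: float = PMMA_RSP) -> CompensatorMap:
    df = pd.read_csv(path)
    for col in ("x_cm", "y_cm", "thickness_cm"):
        if col not in df.columns:
            raise InvalidInputError(f"thickness CSV missing column {col}")
    xs = np.unique(df["x_cm"].to_numpy())
    ys = np.unique(df["y_cm"].to_numpy())
    t = (
        df.pivot(index="x_cm", columns="y_cm", values="thickness_cm")
        .reindex(index=xs, columns=ys)
        .to_numpy()
    )
    if np.isnan(t).any():
        raise InvalidInputError("thickness CSV is not a complete lattice")
    dx = np.diff(xs)
    if xs.size > 1 and not np.allclose(dx, dx[0]):
        raise InvalidInputError("thickness CSV x coordinates are not uniform")
    spacing = float(dx[0]) if xs.size > 1 else 1.0
    center = (float(xs.mean()), float(ys.mean()))
    return CompensatorMap(t, spacing, material_rsp, center)


def export_stl(comp: CompensatorMap, path) -> None:
    """Export the compensator as an ASCII STL solid (triangulated top
    surface over a flat base), mirroring clinical TPS-to-mill workflows."""
    import trimesh

    x, y = comp.cell_coords()
    n, m = comp.thickness.shape
    top = np.array(
        [[x[i] * 10, y[j] * 10, comp.thickness[i, j] * 10.0]
         for i in range(n) for j in range(m)]
    )
    base = top.copy()
    base[:, 2] = 0.0
    vertices = np.vstack([top, base])
    faces = []
    def vid(i, j, layer):
        return layer * n * m + i * m + j
    for i in range(n - 1):
        for j in range(m - 1):
            for layer, flip in ((0, False), (1, True)):
                a, b = vid(i, j, layer), vid(i + 1, j, layer)
                c, d = vid(i + 1, j + 1, layer), vid(i, j + 1, layer)
                tri1, tri2 = [a, b, c], [a, c, d]
                if flip:
                    tri1, tri2 = tri1[::-1], tri2[::-1]
                faces.extend([tri1, tri2])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
    mesh.export(str(path), file_type="stl_ascii")
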