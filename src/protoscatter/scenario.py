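"""End-to-end scenario runner.

One scenario is: generate (or load) a phantom, choose beam range and
modulation to cover the target through the designed compensator, design
that compensator, run the verification-plan workflow, and report the
scatter factors together with the field composition and the compensator
irregularity metric — one row of the runs table the empirical models are
fitted on.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidInputError
from .materials import RspCalibration, default_calibration
from .phantoms import (
    DEFAULT_BEV_RADIUS_MM,
    HUGrid,
    TargetSpec,
    bev_cylinder_mask,
    make_lung_phantom,
    make_pelvis_phantom,
    make_water_box,
)
from .engine import BeamSpec, Ray, trace_path
from .compensator import compensator_iqr, design_compensator, scatter_radius
from .composition import composition_breakdown
from .pipeline import compute_scatter_factors

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one scenario run."""

    phantom_kind: str = "water"  # water | lung | pelvis
    heterogeneity_fraction: float = 0.0  # air (lung) or dense bone (pelvis)
    seed: int = 0
    shape: tuple[int, int, int] = (100, 100, 100)
    spacing_mm: float = 3.0
    bev_radius_mm: float = DEFAULT_BEV_RADIUS_MM
    field_radius_cm: float = 4.0
    beamlet_spacing_cm: float = 0.4
    source_sigma_cm: float = 0.4
    sad_cm: float = 200.0
    air_gap_cm: float = 5.0
    modulation_margin_cm: float = 0.5
    point_shift_mm: float = 0.0  # axial shift of the calculation point

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def choose_beam(grid: HUGrid, target: TargetSpec, cal: RspCalibration,
                config: RunConfig) -> BeamSpec:
    """Pick range and modulation from the target geometry.

    The range is the largest distal-target WED over the beam's-eye rays
    (so the designed compensator is non-negative with a zero minimum); the
    modulation reaches back past the proximal target edge on the central
    axis with a margin, keeping the mid-target calculation point on the
    SOBP plateau with and without the compensator.
    """
    iso = target.centroid
    source = iso + np.array([0.0, 0.0, -config.sad_cm * 10.0])
    axis = Ray(source, np.array([0.0, 0.0, 1.0]))
    zt = np.where(target.mask.any(axis=(0, 1)))[0]
    sz = grid.spacing[2]
    z_prox = grid.origin[2] + zt[0] * sz
    wed_prox = trace_path(grid, axis, cal, z_prox - source[2])[0]

    # sample distal WED over a coarse lateral fan
    span = config.field_radius_cm
    best = 0.0
    for u in np.linspace(-span, span, 9):
        for v in np.linspace(-span, span, 9):
            if u**2 + v**2 > span**2:
                continue
            q = iso + np.array([u * 10.0, v * 10.0, 0.0])
            d = q - source
            d = d / np.linalg.norm(d)
            lengths, idx = _segments(grid, source, d)
            if lengths.size == 0:
                continue
            hit = target.mask[idx]
            if not hit.any():
                continue
            last = np.where(hit)[0][-1]
            rsp = cal.rsp(grid.values[idx][: last + 1])
            best = max(best, float(np.dot(lengths[: last + 1] / 10.0, rsp)))
    if best <= 0:
        raise InvalidInputError("beam does not intersect the target")
    range_cm = best + 0.2
    modulation = min(range_cm, range_cm - wed_prox + config.modulation_margin_cm)
    return BeamSpec(
        range_cm=range_cm,
        modulation_cm=modulation,
        field_radius_cm=config.field_radius_cm,
        sad_cm=config.sad_cm,
        air_gap_cm=config.air_gap_cm,
        beamlet_spacing_cm=config.beamlet_spacing_cm,
        source_sigma_cm=config.source_sigma_cm,
    )


def _segments(grid, origin, direction):
    from . import engine

    return engine._ray_segments(grid, origin, direction)


def build_phantom(config: RunConfig):
    shape = tuple(config.shape)
    spacing = (config.spacing_mm,) * 3
    if config.phantom_kind == "water":
        return make_water_box(shape, spacing)
    if config.phantom_kind == "lung":
        return make_lung_phantom(
            config.heterogeneity_fraction, config.seed, shape, spacing,
            bev_radius_mm=config.bev_radius_mm,
        )
    if config.phantom_kind == "pelvis":
        return make_pelvis_phantom(
            config.heterogeneity_fraction, config.seed, shape, spacing,
            bev_radius_mm=config.bev_radius_mm,
        )
    raise InvalidInputError(f"unknown phantom kind {config.phantom_kind!r}")


def run_scenario(config: RunConfig, cal: RspCalibration | None = None) -> dict:
    """Run one phantom scenario end to end; returns a flat result row.

    The row carries the scatter factors, the BEV composition percentages,
    the compensator IQR inside the Highland scattering radius, and
    provenance (seed, config hash) — everything the empirical models need.
    """
    cal = cal or default_calibration()
    grid, target = build_phantom(config)
    beam = choose_beam(grid, target, cal, config)
    comp = design_compensator(grid, beam, target, cal)

    point = np.asarray(target.centroid, float)
    if config.point_shift_mm:
        point = point + np.array([0.0, 0.0, config.point_shift_mm])
    factors = compute_scatter_factors(grid, beam, comp, target, cal, point_mm=point)

    bev = bev_cylinder_mask(grid, config.bev_radius_mm)
    comp_breakdown = composition_breakdown(grid, bev)
    depth_cm = (point[2] - grid.origin[2]) / 10.0
    radius = scatter_radius(beam, comp, depth_cm)
    iqr = compensator_iqr(comp, max(radius, 2.5 * comp.lateral_spacing_cm))

    row = {
        "phantom_kind": config.phantom_kind,
        "heterogeneity_fraction": config.heterogeneity_fraction,
        "seed": config.seed,
        "range_cm": beam.range_cm,
        "modulation_cm": beam.modulation_cm,
        "psf": factors.psf,
        "csf": factors.csf,
        "cpsf": factors.cpsf,
        "wed_cm": factors.wed_cm,
        "air_pct": comp_breakdown.air_pct,
        "dense_bone_pct": comp_breakdown.dense_bone_pct,
        "iqr_cm": iqr.iqr_cm,
        "scatter_radius_cm": radius,
        "config_hash": config.config_hash(),
    }
    log.info("scenario %s: psf=%.4f csf=%.4f", config.config_hash(), factors.psf,
             factors.csf)
    return row
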