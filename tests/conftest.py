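import numpy as np
import pytest

import protoscatter as ps
from protoscatter.engine import BeamSpec


@pytest.fixture(scope="session")
def cal():
    return ps.default_calibration()


@pytest.fixture(scope="session")
def water_small():
    """Small water box used across engine/pipeline tests."""
    return ps.make_water_box(shape=(72, 72, 72), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def beam_small():
    """Coarse-lattice beam matched to the small water box."""
    return BeamSpec(
        range_cm=18.0,
        modulation_cm=8.0,
        field_radius_cm=3.5,
        beamlet_spacing_cm=0.4,
    )


def fine_step_wed(grid, origin, direction, cal, stop_cm=None, step_mm=0.02):
    """Independent WED oracle: midpoint Riemann sum at a fixed fine step,
    sampling the voxel HU at each midpoint. No shared code with the exact
    boundary traversal."""
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    gmin = np.asarray(grid.origin, float)
    gmax = gmin + grid.extent_mm
    t_lo, t_hi = 0.0, np.inf
    for ax in range(3):
        if d[ax] == 0:
            if not (gmin[ax] <= o[ax] <= gmax[ax]):
                return 0.0
        else:
            t1 = (gmin[ax] - o[ax]) / d[ax]
            t2 = (gmax[ax] - o[ax]) / d[ax]
            t_lo = max(t_lo, min(t1, t2))
            t_hi = min(t_hi, max(t1, t2))
    if stop_cm is not None:
        t_hi = min(t_hi, stop_cm * 10.0)
    if t_hi <= t_lo:
        return 0.0
    ts = np.arange(t_lo + step_mm / 2, t_hi, step_mm)
    pts = o[None, :] + ts[:, None] * d[None, :]
    idx = np.floor((pts - gmin[None, :]) / np.asarray(grid.spacing)).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    hu = grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.sum(cal.rsp(hu)) * step_mm / 10.0)
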