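import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protoscatter as ps
from protoscatter.composition import (
    composition_breakdown,
    hu_histogram,
    isodose_mask,
)
from protoscatter.errors import DegeneratePlanError, InsufficientDataError
from protoscatter.phantoms import bev_cylinder_mask


class TestIsodose:
    def test_max_voxel_always_included(self):
        rng = np.random.default_rng(0)
        dose = rng.random((10, 10, 10))
        mask = isodose_mask(dose, 0.5)
        assert mask[np.unravel_index(np.argmax(dose), dose.shape)]

    def test_fraction_zero_is_positive_support(self):
        dose = np.zeros((5, 5, 5))
        dose[2, 2, 2] = 1.0
        dose[0, 0, 0] = 0.1
        assert isodose_mask(dose, 0.0).sum() == 2

    def test_fraction_one_is_argmax_set(self):
        dose = np.zeros((5, 5, 5))
        dose[1, 1, 1] = 2.0
        dose[3, 3, 3] = 2.0
        dose[2, 2, 2] = 1.0
        assert isodose_mask(dose, 1.0).sum() == 2

    def test_all_zero_dose_rejected(self):
        with pytest.raises(DegeneratePlanError):
            isodose_mask(np.zeros((4, 4, 4)), 0.5)


class TestBreakdown:
    def test_constructed_lung_like_composition(self):
        """A region built as 32% HU -800, 62% HU 0, 6% HU 300 decomposes
        into exactly those air/soft/bone fractions."""
        vals = np.zeros((10, 10, 50), dtype=np.int16)
        vals[:, :, :16] = -800
        vals[:, :, 16:47] = 0
        vals[:, :, 47:] = 300
        grid = ps.HUGrid(vals, (2, 2, 2))
        br = composition_breakdown(grid, np.ones(grid.shape, bool))
        assert br.air == pytest.approx(0.32, abs=1e-12)
        assert br.soft_tissue == pytest.approx(0.62, abs=1e-12)
        assert br.bone == pytest.approx(0.06, abs=1e-12)
        assert br.thin_tissue == 0.0 and br.dense_bone == 0.0

    def test_constructed_pelvis_like_composition(self):
        """80.8% soft, 15.1% bone, 4.1% dense bone, 0% air."""
        n = 1000
        vals = np.zeros((10, 10, 10), dtype=np.int16).ravel()
        vals[:41] = 700
        vals[41 : 41 + 151] = 300
        grid = ps.HUGrid(vals.reshape(10, 10, 10), (2, 2, 2))
        br = composition_breakdown(grid, np.ones(grid.shape, bool))
        assert br.soft_tissue == pytest.approx(0.808, abs=1e-12)
        assert br.bone == pytest.approx(0.151, abs=1e-12)
        assert br.dense_bone == pytest.approx(0.041, abs=1e-12)
        assert br.air == 0.0
        del n

    def test_all_water_mask(self):
        grid, _ = ps.make_water_box(shape=(20, 20, 20))
        br = composition_breakdown(grid, np.ones(grid.shape, bool))
        assert br.soft_tissue == 1.0

    def test_empty_mask_rejected(self):
        grid, _ = ps.make_water_box(shape=(12, 12, 12))
        with pytest.raises(InsufficientDataError):
            composition_breakdown(grid, np.zeros(grid.shape, bool))

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_fractions_sum_to_one_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(-1024, 3001, size=(8, 8, 8)).astype(np.int16)
        grid = ps.HUGrid(vals, (2, 2, 2))
        mask = rng.random((8, 8, 8)) < 0.5
        if not mask.any():
            mask[0, 0, 0] = True
        br = composition_breakdown(grid, mask)
        assert br.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_translation_with_grid(self):
        """Rolling grid and mask together leaves the breakdown unchanged."""
        rng = np.random.default_rng(3)
        vals = rng.integers(-1000, 1246, size=(12, 12, 12)).astype(np.int16)
        grid = ps.HUGrid(vals, (2, 2, 2))
        mask = rng.random((12, 12, 12)) < 0.3
        mask[0, 0, 0] = True
        br1 = composition_breakdown(grid, mask)
        rolled = ps.HUGrid(np.roll(vals, 4, axis=2), (2, 2, 2))
        br2 = composition_breakdown(rolled, np.roll(mask, 4, axis=2))
        assert np.allclose(br1.as_array(), br2.as_array())

    def test_closed_loop_with_lung_generator(self):
        """Requested generator fractions are recovered by the breakdown."""
        for frac in (0.1, 0.32):
            grid, _ = ps.make_lung_phantom(frac, seed=7, shape=(72, 72, 72),
                                           spacing=(4, 4, 4), bev_radius_mm=40.0)
            br = composition_breakdown(grid, bev_cylinder_mask(grid, 40.0))
            assert br.air == pytest.approx(frac, abs=0.02)


def test_histogram_shows_material_peaks():
    grid, _ = ps.make_lung_phantom(0.3, seed=1, shape=(60, 60, 60),
                                   spacing=(4, 4, 4))
    df = hu_histogram(grid, np.ones(grid.shape, bool), bin_width=50)
    top = df.nlargest(2, "count")["hu"].tolist()
    assert any(abs(h + 800) <= 50 for h in top)  # air-pocket peak
    assert any(abs(h) <= 50 for h in top)        # soft-tissue peak


def test_isodose_region_from_dose_grid(cal):
    """The 50% isodose region of a computed water dose covers the SOBP
    plateau around the target and is soft tissue throughout."""
    from protoscatter.engine import BeamSpec, dose_grid

    grid, tgt = ps.make_water_box(shape=(50, 50, 50), spacing=(4, 4, 4))
    beam = BeamSpec(range_cm=12.0, modulation_cm=5.0, field_radius_cm=3.0,
                    beamlet_spacing_cm=0.4)
    dose, (xs, ys, zs) = dose_grid(grid, beam, None, cal, isocenter_mm=tgt.centroid,
                                   lateral_step_cm=0.8, depth_step_cm=0.8)
    mask = isodose_mask(dose, 0.5)
    assert mask.any()
    k_mid = int(np.argmin(np.abs(zs - tgt.centroid[2])))
    i_mid = int(np.argmin(np.abs(xs - tgt.centroid[0])))
    j_mid = int(np.argmin(np.abs(ys - tgt.centroid[1])))
    assert mask[i_mid, j_mid, k_mid]
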