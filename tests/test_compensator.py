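import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protoscatter as ps
from protoscatter.compensator import (
    CompensatorMap,
    compensator_iqr,
    design_compensator,
    make_rippled_compensator,
    read_thickness_csv,
    scatter_radius,
    write_thickness_csv,
)
from protoscatter.engine import BeamSpec, Ray, wed_along_ray
from protoscatter.errors import InsufficientDataError, InvalidInputError


@pytest.fixture(scope="module")
def flat_target_setup(cal):
    """Water phantom with a flat distal target face at 14.4 cm depth."""
    grid, _ = ps.make_water_box(shape=(60, 60, 60), spacing=(4, 4, 4))
    mask = np.zeros((60, 60, 60), bool)
    mask[15:45, 15:45, 24:36] = True  # distal face at z index 36 -> 14.4 cm
    target = ps.TargetSpec(mask, _grid=grid)
    return grid, target


class TestDesign:
    def test_uniform_thickness_by_hand(self, cal, flat_target_setup):
        """R = distal WED + 2.32 cm on water gives (R-d)/1.16 = 2.0 cm."""
        grid, target = flat_target_setup
        beam = BeamSpec(range_cm=14.4 + 2.32, modulation_cm=6.0,
                        field_radius_cm=4.0, beamlet_spacing_cm=0.4)
        comp = design_compensator(grid, beam, target, cal)
        assert np.median(comp.thickness) == pytest.approx(2.0, abs=0.02)
        assert comp.thickness.max() - comp.thickness.min() < 0.05

    def test_monotone_rule_deeper_edge_thinner(self, cal):
        """A ray with a deeper distal target edge gets a thinner
        compensator than one with a shallower edge."""
        grid, _ = ps.make_water_box(shape=(60, 60, 60), spacing=(4, 4, 4))
        mask = np.zeros((60, 60, 60), bool)
        mask[10:30, 15:45, 24:36] = True   # left half: distal 14.4 cm
        mask[30:50, 15:45, 24:30] = True   # right half: distal 12.0 cm
        target = ps.TargetSpec(mask, _grid=grid)
        beam = BeamSpec(range_cm=16.0, modulation_cm=6.0, field_radius_cm=4.5,
                        beamlet_spacing_cm=0.4)
        comp = design_compensator(grid, beam, target, cal)
        left = comp.thickness_at(-2.0, 0.0)
        right = comp.thickness_at(2.0, 0.0)
        assert left < right

    def test_range_shorter_than_target_warns_all_zero(self, cal, flat_target_setup):
        grid, target = flat_target_setup
        beam = BeamSpec(range_cm=9.6, modulation_cm=4.0, field_radius_cm=4.0,
                        beamlet_spacing_cm=0.4)
        with pytest.warns(UserWarning, match="all zero"):
            comp = design_compensator(grid, beam, target, cal)
        assert np.all(comp.thickness == 0.0)

    def test_closure_thickness_plus_distal_wed_equals_range(self, cal,
                                                            flat_target_setup):
        """t * rsp_comp + WED to the distal target edge recovers the
        prescribed range within one voxel's water-equivalent thickness."""
        grid, target = flat_target_setup
        beam = BeamSpec(range_cm=16.0, modulation_cm=6.0, field_radius_cm=4.0,
                        beamlet_spacing_cm=0.4)
        comp = design_compensator(grid, beam, target, cal)
        iso = target.centroid
        source = iso + np.array([0.0, 0.0, -beam.sad_cm * 10.0])
        voxel_wet = grid.spacing[2] / 10.0 * 1.1
        for u, v in [(0.0, 0.0), (2.0, 1.0), (-3.0, -2.0)]:
            q = iso + np.array([u * 10.0, v * 10.0, 0.0])
            d = (q - source) / np.linalg.norm(q - source)
            # distal edge of the target along this ray
            from protoscatter.engine import _ray_segments

            lengths, idx = _ray_segments(grid, source, d)
            hit = target.mask[idx]
            assert hit.any()
            last = np.where(hit)[0][-1]
            rsp = cal.rsp(grid.values[idx][: last + 1])
            wed_distal = float(np.dot(lengths[: last + 1] / 10.0, rsp))
            t = float(comp.thickness_at(u, v))
            assert t * comp.material_rsp + wed_distal == pytest.approx(
                beam.range_cm, abs=voxel_wet
            )


class TestIqr:
    def test_constant_map_zero_iqr(self):
        comp = CompensatorMap(np.full((15, 15), 3.0), 0.5)
        assert compensator_iqr(comp, 2.0).iqr_cm == 0.0

    def test_four_samples_order_statistics(self):
        """{1,2,3,4} cm has IQR 1.5 under linear order-statistic
        interpolation (Q1 = 1.75, Q3 = 3.25)."""
        comp = CompensatorMap(np.array([[1.0, 2.0], [3.0, 4.0]]), 1.0)
        m = compensator_iqr(comp, 2.0)
        assert m.iqr_cm == pytest.approx(1.5, rel=1e-12)
        assert m.n_samples == 4

    def test_insufficient_samples_raises(self):
        comp = CompensatorMap(np.ones((9, 9)), 1.0)
        with pytest.raises(InsufficientDataError):
            compensator_iqr(comp, 0.5)

    @settings(deadline=None, max_examples=25)
    @given(
        shift=st.floats(0.0, 5.0),
        scale=st.floats(0.1, 4.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_translation_and_scale_invariance(self, shift, scale, seed):
        """Adding a uniform slab leaves the IQR unchanged; scaling the
        thickness scales the IQR linearly."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 3.0, size=(13, 13))
        c0 = CompensatorMap(base, 0.5)
        c_shift = CompensatorMap(base + shift, 0.5)
        c_scale = CompensatorMap(base * scale, 0.5)
        i0 = compensator_iqr(c0, 2.5).iqr_cm
        assert compensator_iqr(c_shift, 2.5).iqr_cm == pytest.approx(i0, abs=1e-12)
        assert compensator_iqr(c_scale, 2.5).iqr_cm == pytest.approx(
            scale * i0, rel=1e-9
        )


class TestScatterRadius:
    def test_regression_value(self):
        """Median 4 cm PMMA, R 15 cm (E ~ 146.5 MeV), drift 15 cm."""
        beam = BeamSpec(range_cm=15.0, modulation_cm=5.0, air_gap_cm=5.0)
        comp = CompensatorMap(np.full((21, 21), 4.0), 0.4)
        assert scatter_radius(beam, comp, 10.0) == pytest.approx(0.71302, abs=2e-4)

    def test_thickness_floor_for_empty_map(self):
        beam = BeamSpec(range_cm=15.0, modulation_cm=5.0, air_gap_cm=5.0)
        comp0 = CompensatorMap(np.zeros((11, 11)), 0.4)
        thin = CompensatorMap(np.full((11, 11), 0.1), 0.4)
        assert scatter_radius(beam, comp0, 10.0) == scatter_radius(beam, thin, 10.0)
        assert scatter_radius(beam, comp0, 10.0) > 0

    def test_increases_with_air_gap(self):
        comp = CompensatorMap(np.full((11, 11), 2.0), 0.4)
        r = [
            scatter_radius(
                BeamSpec(range_cm=15.0, modulation_cm=5.0, air_gap_cm=g), comp, 10.0
            )
            for g in (2.0, 5.0, 10.0)
        ]
        assert r[0] < r[1] < r[2]


def test_rippled_family_iqr_monotone():
    amps = [0.0, 0.5, 1.0, 1.5, 2.0]
    iqrs = [
        compensator_iqr(make_rippled_compensator(2.0, a, 4.0, 0.4), 2.0).iqr_cm
        for a in amps
    ]
    assert all(b > a for a, b in zip(iqrs, iqrs[1:]))


def test_thickness_csv_round_trip(tmp_path):
    comp = make_rippled_compensator(2.0, 1.0, 3.0, 0.5)
    path = tmp_path / "comp.csv"
    write_thickness_csv(comp, path)
    back = read_thickness_csv(path)
    assert np.allclose(back.thickness, comp.thickness)
    assert back.lateral_spacing_cm == pytest.approx(comp.lateral_spacing_cm)


def test_stl_export_ascii(tmp_path):
    comp = make_rippled_compensator(1.0, 0.5, 2.0, 0.5)
    path = tmp_path / "comp.stl"
    from protoscatter.compensator import export_stl

    export_stl(comp, path)
    head = path.read_text()[:80]
    assert head.startswith("solid")
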