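"""Segment volumes, s-curve weighting and the AIF statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aifmap import (PolarMap, SCurveParams, compute_aif, model_aif,
                    relative_levels, s_curve_weight, segment_volume)
from aifmap.aifcore import segment_levels_from_sweep
from aifmap.io import default_mouse_geometry


class TestSegmentVolume:
    def test_direct_arithmetic(self):
        assert segment_volume(6, 4.0, 2.0, 1.0) == pytest.approx(
            8.0 * np.pi / 6.0)

    def test_vanishing_thickness(self):
        assert segment_volume(6, 4.0, 2.0, 1e-12) == pytest.approx(0.0,
                                                                   abs=1e-9)

    def test_ring_sum_independent_of_segment_count(self):
        # N_s cancels when summing a full ring
        total = 6 * segment_volume(6, 4.0, 2.0, 1.0)
        assert total == pytest.approx(np.pi * 4.0 * 2.0 * 1.0)

    def test_non_positive_dimension_rejected(self):
        with pytest.raises(ValueError):
            segment_volume(6, -1.0, 2.0, 1.0)


class TestRelativeLevels:
    def test_equal_values_all_one(self):
        assert np.allclose(relative_levels([5.0] * 20), 1.0)

    def test_ratio_definition(self):
        levels = relative_levels([100.0, 55.0, 10.0])
        assert np.allclose(levels, [1.0, 0.55, 0.10])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.1, 1.0, size=20)
        perm = rng.permutation(20)
        assert np.allclose(relative_levels(values)[perm],
                           relative_levels(values[perm]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_levels(np.zeros(20))


class TestSCurveWeight:
    def test_inflection_point_is_half(self):
        assert s_curve_weight(0.55, SCurveParams(0.55, 9)) == pytest.approx(
            0.5)

    def test_zero_level_is_one(self):
        assert s_curve_weight(0.0, SCurveParams(0.55, 9)) == 1.0

    def test_normal_level_weight(self):
        # 1 / (1 + (1/0.55)^18)
        expected = 1.0 / (1.0 + (1.0 / 0.55) ** 18)
        assert s_curve_weight(1.0, SCurveParams(0.55, 9)) == pytest.approx(
            expected, rel=1e-9)
        assert expected == pytest.approx(2.1e-5, rel=0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            s_curve_weight(1.2, SCurveParams())

    def test_no_overflow_at_extreme_exponent(self):
        # large n exercises the log-space evaluation
        w = s_curve_weight(1.0, SCurveParams(0.1, 90.0))
        assert 0.0 <= w < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(u1=st.floats(0.0, 1.0), u2=st.floats(0.0, 1.0))
    def test_monotone_decreasing(self, u1, u2):
        """Non-increasing everywhere; strictly decreasing where the weight
        is not saturated at floating-point 1 or 0."""
        from hypothesis import assume

        p = SCurveParams(0.55, 9)
        if u1 > u2:
            u1, u2 = u2, u1
        w1, w2 = s_curve_weight(u1, p), s_curve_weight(u2, p)
        assert w1 >= w2
        assume(u2 - u1 > 1e-3 and 1e-12 < w1 < 1.0 - 1e-12)
        assert w1 > w2


class TestComputeAif:
    @pytest.fixture()
    def geometry(self):
        return default_mouse_geometry()

    def test_total_defect_gives_one(self, geometry):
        # level 0 everywhere except one hot segment sets the scale
        values = np.zeros(20)
        values[0] = 1.0
        pmap = PolarMap(values)
        result = compute_aif(pmap, geometry, SCurveParams(0.55, 9))
        # 19 segments at P=1, one at P(1)~0
        v = geometry.volumes
        expected = (v.sum() - v[0]) / v.sum()
        assert result.aif == pytest.approx(expected, abs=1e-4)

    def test_normal_map_gives_near_zero(self, geometry):
        result = compute_aif(PolarMap(np.ones(20)), geometry)
        assert result.aif == pytest.approx(0.0, abs=1e-4)

    def test_equal_volumes_reduce_to_plain_mean(self):
        rows = []
        for sid in range(1, 21):
            ring = ("basal" if sid <= 6 else "middle" if sid <= 12
                    else "apical" if sid <= 18 else "apex")
            n_s = 2 if ring == "apex" else 6
            rows.append({"segment_id": sid, "ring": ring, "N_s": n_s,
                         "D_s": 1.0 * n_s, "L_s": 1.0, "T_s": 1.0})
        from aifmap import SegmentGeometryTable

        geom = SegmentGeometryTable(pd.DataFrame(rows))
        assert np.allclose(geom.volumes, geom.volumes[0])
        rng = np.random.default_rng(1)
        values = rng.uniform(0.2, 1.0, 20)
        result = compute_aif(PolarMap(values), geom)
        expected = np.mean(s_curve_weight(relative_levels(values),
                                          SCurveParams()))
        assert result.aif == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_of_geometry(self, geometry):
        rng = np.random.default_rng(2)
        pmap = PolarMap(rng.uniform(0.1, 1.0, 20))
        a1 = compute_aif(pmap, geometry).aif
        a2 = compute_aif(pmap, geometry.scaled(2.0)).aif
        assert a1 == pytest.approx(a2, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seg=st.integers(0, 19), factor=st.floats(0.1, 0.99))
    def test_decreasing_a_level_never_decreases_aif(self, seg, factor):
        geometry = default_mouse_geometry()
        rng = np.random.default_rng(3)
        values = rng.uniform(0.3, 1.0, 20)
        values[np.argmax(values)] = 1.0
        lowered = values.copy()
        lowered[seg] = values[seg] * factor
        base = compute_aif(PolarMap(values), geometry).aif
        # lowering a non-maximal segment's uptake (renormalization may
        # change the hottest segment only if seg was the max; skip then)
        if lowered.max() == values.max():
            worse = compute_aif(PolarMap(lowered), geometry).aif
            assert worse >= base - 1e-12

    def test_bounds(self, geometry):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pmap = PolarMap(rng.uniform(0.01, 1.0, 20))
            aif = compute_aif(pmap, geometry).aif
            assert 0.0 <= aif <= 1.0


class TestModelAif:
    def test_defect_free_near_zero(self):
        assert model_aif(np.ones(6)) == pytest.approx(0.0, abs=1e-4)

    def test_aligned_240_degree_defect(self):
        # 4 segments dead, 2 normal: Eq. 5 by hand gives (4 + 2 P(1)) / 6
        levels = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
        p1 = s_curve_weight(1.0, SCurveParams(0.55, 9))
        assert model_aif(levels) == pytest.approx((4.0 + 2.0 * p1) / 6.0,
                                                  rel=1e-9)
        assert model_aif(levels) == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_ideal_model_matches_truth(self, curve_ideal_240):
        """Ideal tomography, defect aligned to the segmentation: the model
        AIF equals the analytic infarcted fraction."""
        levels = segment_levels_from_sweep(curve_ideal_240.center_angles,
                                           curve_ideal_240.levels)
        assert model_aif(levels) == pytest.approx(240.0 / 360.0, abs=0.01)


class TestSegmentLevelsFromSweep:
    def test_picks_and_renormalizes(self):
        centers = np.arange(0.0, 360.0, 1.0)
        acts = np.where(np.isin(centers, [30, 90, 150, 210, 270, 330]),
                        [50.0] * 360, 1.0)
        acts[90] = 100.0
        levels = segment_levels_from_sweep(centers, acts)
        assert levels.max() == 1.0
        assert levels[1] == 1.0  # segment centred at 90
        assert np.allclose(np.delete(levels, 1), 0.5)
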