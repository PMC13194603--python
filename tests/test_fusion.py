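import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvct.fusion import (
    DifferenceMaps,
    WeightMaps,
    average_fuse,
    cycle_difference_maps,
    fuse_with_cycle_weights,
    weight_maps_from_diffs,
    weighted_fuse,
)

identity = lambda x: x  # noqa: E731


def const_maps(va, vs, vc, shape=(4, 4)):
    return DifferenceMaps(
        np.full(shape, float(va)), np.full(shape, float(vs)), np.full(shape, float(vc))
    )


class TestDifferenceMaps:
    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DifferenceMaps(np.full((2, 2), -1.0), np.zeros((2, 2)), np.zeros((2, 2)))

    def test_total_is_elementwise_sum(self, rng):
        a, s, c = (np.abs(rng.normal(size=(3, 3))) for _ in range(3))
        d = DifferenceMaps(a, s, c)
        np.testing.assert_allclose(d.total, a + s + c)


class TestCycleDifferenceMaps:
    def test_perfect_reconstruction_zero(self, rng):
        ref = rng.normal(size=(5, 5))
        d = cycle_difference_maps((ref, ref, ref), ref, identity)
        for m in (d.diff_a, d.diff_s, d.diff_c):
            np.testing.assert_array_equal(m, np.zeros_like(ref))

    def test_constant_offsets(self, rng):
        ref = rng.normal(size=(4, 4))
        d = cycle_difference_maps((ref + 0, ref + 1, ref + 2), ref, identity)
        np.testing.assert_allclose(d.diff_a, 0.0)
        np.testing.assert_allclose(d.diff_s, 1.0)
        np.testing.assert_allclose(d.diff_c, 2.0)
        np.testing.assert_allclose(d.total, 3.0)

    def test_pure_function_of_values(self, rng):
        ref = rng.normal(size=(4, 4))
        p = ref + rng.normal(size=(4, 4))
        d1 = cycle_difference_maps((p, p.copy(), p), ref, identity)
        d2 = cycle_difference_maps((p.copy(), p, p.copy()), ref, identity)
        np.testing.assert_array_equal(d1.diff_s, d2.diff_s)

    def test_shape_mismatch_rejected(self, rng):
        ref = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="shape"):
            cycle_difference_maps((ref, ref, ref), ref[:2], identity)


class TestWeightMaps:
    def test_symmetric_diffs_give_uniform_weights(self):
        w = weight_maps_from_diffs(const_maps(1, 1, 1))
        np.testing.assert_allclose(w.w_a, 1 / 3)
        np.testing.assert_allclose(w.w_s, 1 / 3)
        np.testing.assert_allclose(w.w_c, 1 / 3)

    def test_best_view_gets_largest_weight(self):
        # diffs (0,1,1): axial is perfect -> w_a = 1/2, others 1/4
        w = weight_maps_from_diffs(const_maps(0, 1, 1))
        np.testing.assert_allclose(w.w_a, 0.5)
        np.testing.assert_allclose(w.w_s, 0.25)
        np.testing.assert_allclose(w.w_c, 0.25)

    def test_worst_view_gets_smallest_weight(self):
        # diffs (2,1,1): w_a = 1/4, w_s = w_c = 3/8
        w = weight_maps_from_diffs(const_maps(2, 1, 1))
        np.testing.assert_allclose(w.w_a, 0.25)
        np.testing.assert_allclose(w.w_s, 0.375)
        np.testing.assert_allclose(w.w_c, 0.375)

    def test_zero_total_pixels_uniform(self):
        d = DifferenceMaps(
            np.array([[0.0, 1.0]]), np.array([[0.0, 1.0]]), np.array([[0.0, 2.0]])
        )
        w = weight_maps_from_diffs(d)
        assert w.w_a[0, 0] == w.w_s[0, 0] == w.w_c[0, 0] == pytest.approx(1 / 3)
        np.testing.assert_allclose(w.w_a[0, 1] + w.w_s[0, 1] + w.w_c[0, 1], 1.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31))
    def test_property_sum_to_one_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        d = DifferenceMaps(*(np.abs(rng.normal(size=(6, 6))) for _ in range(3)))
        w = weight_maps_from_diffs(d)
        np.testing.assert_allclose(w.w_a + w.w_s + w.w_c, 1.0, atol=1e-12)
        pos = d.total > 0
        for m in (w.w_a, w.w_s, w.w_c):
            assert np.all(m[pos] >= -1e-12)
            assert np.all(m[pos] <= 0.5 + 1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31))
    def test_property_monotone_reliability(self, seed):
        # decreasing one view's difference never decreases that view's weight
        rng = np.random.default_rng(seed)
        a, s, c = (np.abs(rng.normal(size=(4, 4))) + 0.1 for _ in range(3))
        w0 = weight_maps_from_diffs(DifferenceMaps(a, s, c))
        w1 = weight_maps_from_diffs(DifferenceMaps(a * 0.5, s, c))
        assert np.all(w1.w_a >= w0.w_a - 1e-12)


class TestWeightedFuse:
    def test_identical_predictions_fixed_point(self, rng):
        p = rng.normal(size=(4, 4))
        w = weight_maps_from_diffs(
            DifferenceMaps(*(np.abs(rng.normal(size=(4, 4))) for _ in range(3)))
        )
        np.testing.assert_allclose(weighted_fuse((p, p, p), w), p)

    def test_degenerate_one_hot_weights(self, rng):
        pa, ps, pc = (rng.normal(size=(3, 3)) for _ in range(3))
        w = WeightMaps(np.ones((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))
        np.testing.assert_array_equal(weighted_fuse((pa, ps, pc), w), pa)

    def test_constant_arithmetic(self):
        shape = (2, 2)
        preds = (np.full(shape, 0.0), np.full(shape, 4.0), np.full(shape, 8.0))
        w = WeightMaps(np.full(shape, 0.5), np.full(shape, 0.25), np.full(shape, 0.25))
        np.testing.assert_allclose(weighted_fuse(preds, w), 3.0)

    def test_invalid_weight_sum_rejected(self, rng):
        p = rng.normal(size=(2, 2))
        w = WeightMaps(np.full((2, 2), 0.5), np.full((2, 2), 0.5), np.full((2, 2), 0.5))
        with pytest.raises(ValueError, match="sum"):
            weighted_fuse((p, p, p), w)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31))
    def test_property_convex_envelope(self, seed):
        rng = np.random.default_rng(seed)
        preds = tuple(rng.normal(size=(5, 5)) for _ in range(3))
        diffs = DifferenceMaps(*(np.abs(rng.normal(size=(5, 5))) for _ in range(3)))
        fused = weighted_fuse(preds, weight_maps_from_diffs(diffs))
        lo = np.minimum.reduce(preds)
        hi = np.maximum.reduce(preds)
        assert np.all(fused >= lo - 1e-10)
        assert np.all(fused <= hi + 1e-10)


class TestScalarMode:
    def test_scalar_weights_are_constant_maps(self, rng):
        d = DifferenceMaps(*(np.abs(rng.normal(size=(6, 6))) + 0.1 for _ in range(3)))
        w = weight_maps_from_diffs(d, per_pixel=False)
        for m in (w.w_a, w.w_s, w.w_c):
            assert np.ptp(m) == 0.0
        np.testing.assert_allclose(w.w_a + w.w_s + w.w_c, 1.0)

    def test_scalar_mode_matches_mean_diff_formula(self, rng):
        d = DifferenceMaps(*(np.abs(rng.normal(size=(6, 6))) + 0.1 for _ in range(3)))
        w = weight_maps_from_diffs(d, per_pixel=False)
        ma, ms, mc = d.diff_a.mean(), d.diff_s.mean(), d.diff_c.mean()
        np.testing.assert_allclose(w.w_s.flat[0], 0.5 * (ma + mc) / (ma + ms + mc))


class TestAverageFuse:
    def test_constant_mean(self):
        preds = (np.full((2, 2), 0.0), np.full((2, 2), 3.0), np.full((2, 2), 6.0))
        np.testing.assert_allclose(average_fuse(preds), 3.0)

    def test_equals_uniform_weighted_fuse(self, rng):
        preds = tuple(rng.normal(size=(4, 4)) for _ in range(3))
        w = WeightMaps(*(np.full((4, 4), 1 / 3) for _ in range(3)))
        np.testing.assert_allclose(average_fuse(preds), weighted_fuse(preds, w))

    def test_equal_diffs_reproduce_average_bitexact(self, rng):
        preds = tuple(rng.normal(size=(4, 4)) for _ in range(3))
        d = np.abs(rng.normal(size=(4, 4))) + 0.5
        w = weight_maps_from_diffs(DifferenceMaps(d, d.copy(), d.copy()))
        fused = weighted_fuse(preds, w)
        # equal diffs -> each weight exactly (d+d)/(2*3d) = 1/3
        np.testing.assert_allclose(fused, average_fuse(preds), rtol=0, atol=1e-15)


class TestComposition:
    def test_fuse_with_cycle_weights_end_to_end(self, rng):
        ref = rng.normal(size=(6, 6))
        preds = (ref + 0.0, ref + 1.0, ref + 2.0)
        fused, weights, diffs = fuse_with_cycle_weights(preds, ref, identity)
        # diffs (0,1,2): w_a = 1/2, w_s = 1/3, w_c = 1/6
        np.testing.assert_allclose(weights.w_a, 0.5)
        np.testing.assert_allclose(weights.w_s, 1 / 3)
        np.testing.assert_allclose(weights.w_c, 1 / 6)
        np.testing.assert_allclose(fused, ref + (0 * 0.5 + 1 / 3 + 2 / 6))
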