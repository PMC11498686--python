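import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medifuse.detail_fusion import (
    activity_map,
    block_average,
    fuse_detail_contents,
    fuse_details,
    softmax_weights,
    upsample_weights,
)
from medifuse.exceptions import ParameterError, ValidationError
from medifuse.features import extract_features

from oracles import (
    loop_activity_map,
    loop_block_average,
    loop_detail_fusion,
    loop_upsample,
)


class TestActivityMap:
    def test_two_channel_toy_value(self):
        level = np.zeros((2, 1, 1))
        level[0, 0, 0], level[1, 0, 0] = 0.3, -0.4
        assert activity_map(level)[0, 0] == pytest.approx(0.7)

    def test_zero_features_zero_map(self):
        assert np.all(activity_map(np.zeros((4, 5, 5))) == 0)

    def test_matches_per_pixel_loop(self, rng):
        level = rng.standard_normal((4, 5, 5))
        assert np.array_equal(activity_map(level), loop_activity_map(level))


class TestBlockAverage:
    def test_r0_is_identity(self, rng):
        c = rng.random((6, 7))
        assert np.array_equal(block_average(c, 0), c)

    def test_constant_map_interior_and_corner(self):
        c = np.full((7, 7), 0.9)
        out = block_average(c, 1)
        assert out[3, 3] == pytest.approx(0.9)
        assert out[0, 0] == pytest.approx(4 * 0.9 / 9)  # 4 of 9 cells in frame

    def test_matches_zero_padded_box_oracle(self, rng):
        c = rng.random((7, 7))
        # summation order may differ from the loop oracle by one ulp
        assert np.max(np.abs(block_average(c, 1)
                             - loop_block_average(c, 1))) < 1e-12

    def test_negative_radius_rejected(self):
        with pytest.raises(ParameterError):
            block_average(np.zeros((4, 4)), -1)


class TestSoftmaxWeights:
    def test_equal_maps_give_half(self):
        w = softmax_weights([np.ones((3, 3)), np.ones((3, 3))])
        assert np.allclose(w[0], 0.5) and np.allclose(w[1], 0.5)

    def test_three_to_one_ratio(self):
        w = softmax_weights([np.full((2, 2), 3.0), np.full((2, 2), 1.0)])
        assert np.allclose(w[0], 0.75) and np.allclose(w[1], 0.25)

    def test_all_zero_pixel_gets_uniform_tie_rule(self):
        a = np.zeros((2, 2)); a[0, 0] = 2.0
        b = np.zeros((2, 2)); b[0, 0] = 1.0
        w = softmax_weights([a, b])
        assert w[0][1, 1] == 0.5 and w[1][1, 1] == 0.5
        assert w[0][0, 0] == pytest.approx(2 / 3)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValidationError):
            softmax_weights([np.full((2, 2), -0.1), np.ones((2, 2))])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_weights_always_sum_to_one(self, seed):
        g = np.random.default_rng(seed)
        maps = [g.random((5, 6)) * (g.random((5, 6)) > 0.3) for _ in range(2)]
        w = softmax_weights(maps)
        assert np.allclose(w[0] + w[1], 1.0, atol=0)


class TestUpsampleWeights:
    def test_level1_is_identity(self, rng):
        w = rng.random((5, 5))
        assert np.array_equal(upsample_weights(w, (5, 5), 1), w)

    def test_level3_fills_4x4_blocks(self):
        w = np.array([[0.1, 0.9], [0.4, 0.6]])
        up = upsample_weights(w, (8, 8), 3)
        assert np.all(up[:4, :4] == 0.1) and np.all(up[:4, 4:] == 0.9)
        assert np.all(up[4:, :4] == 0.4) and np.all(up[4:, 4:] == 0.6)

    def test_odd_target_matches_index_oracle(self, rng):
        w = rng.random((4, 4))  # level 2, target 7x7
        up = upsample_weights(w, (7, 7), 2)
        assert np.array_equal(up, loop_upsample(w, (7, 7), 2))

    def test_incompatible_target_rejected(self, rng):
        with pytest.raises(ParameterError):
            upsample_weights(rng.random((4, 4)), (20, 20), 2)

    def test_sum_to_one_preserved_exactly(self, rng):
        a = rng.random((4, 4))
        w1, w2 = softmax_weights([a, rng.random((4, 4))])
        u1 = upsample_weights(w1, (7, 7), 2)
        u2 = upsample_weights(w2, (7, 7), 2)
        assert np.all(u1 + u2 == 1.0)


class TestFuseDetailContents:
    def _random_case(self, rng, shape=(6, 6)):
        details = [rng.standard_normal(shape), rng.standard_normal(shape)]
        weight_maps = []
        for _ in range(4):
            w1 = rng.random(shape)
            weight_maps.append([w1, 1.0 - w1])
        return details, weight_maps

    def test_identical_details_fixed_point(self, rng):
        d = rng.standard_normal((6, 6))
        details, weight_maps = [d, d.copy()], []
        for _ in range(4):
            w1 = rng.random((6, 6))
            weight_maps.append([w1, 1.0 - w1])
        res = fuse_detail_contents(details, weight_maps)
        for lvl in res.per_level:
            assert np.allclose(lvl, d, atol=1e-12)
        assert np.allclose(res.combined, d, atol=1e-12)

    def test_degenerate_weights_select_first_source(self, rng):
        details = [rng.standard_normal((6, 6)), rng.standard_normal((6, 6))]
        wm = [[np.ones((6, 6)), np.zeros((6, 6))] for _ in range(4)]
        res = fuse_detail_contents(details, wm)
        assert np.array_equal(res.combined, details[0])

    def test_matches_per_pixel_oracle(self, rng):
        details, weight_maps = self._random_case(rng)
        res = fuse_detail_contents(details, weight_maps)
        per_level, combined = loop_detail_fusion(details, weight_maps)
        for got, want in zip(res.per_level, per_level):
            assert np.max(np.abs(got - want)) < 1e-12
        assert np.array_equal(
            res.combined, np.maximum.reduce(res.per_level))
        assert np.max(np.abs(res.combined - combined)) < 1e-12

    def test_convexity_bound_per_level_and_combined(self, rng):
        details, weight_maps = self._random_case(rng)
        res = fuse_detail_contents(details, weight_maps)
        lo = np.minimum(details[0], details[1])
        hi = np.maximum(details[0], details[1])
        for lvl in res.per_level + [res.combined]:
            assert np.all(lvl >= lo - 1e-12) and np.all(lvl <= hi + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            fuse_detail_contents(
                [rng.random((6, 6)), rng.random((5, 6))],
                [[np.ones((6, 6)), np.zeros((6, 6))]] * 4)


class TestFullDetailBranch:
    def test_permutation_equivariance(self, rng, fixture_extractor):
        d1 = rng.standard_normal((32, 32)) * 0.1
        d2 = rng.standard_normal((32, 32)) * 0.1
        stacks = [extract_features(d, fixture_extractor) for d in (d1, d2)]
        fwd = fuse_details([d1, d2], stacks)
        rev = fuse_details([d2, d1], stacks[::-1])
        assert np.array_equal(fwd.combined, rev.combined)

    def test_deterministic_across_runs(self, rng, fixture_extractor):
        d1 = rng.standard_normal((33, 41)) * 0.1
        d2 = rng.standard_normal((33, 41)) * 0.1
        runs = []
        for _ in range(2):
            stacks = [extract_features(d, fixture_extractor)
                      for d in (d1, d2)]
            runs.append(fuse_details([d1, d2], stacks).combined)
        assert np.array_equal(runs[0], runs[1])
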