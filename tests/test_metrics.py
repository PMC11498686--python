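import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from medifuse.exceptions import (
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from medifuse.metrics import evaluate, mse, psnr, q_m, q_mi, ssim

from oracles import loop_block_average  # noqa: F401  (module import sanity)


def _loop_mse(a255, b255):
    total = 0.0
    h, w = a255.shape
    for y in range(h):
        for x in range(w):
            total += (a255[y, x] - b255[y, x]) ** 2
    return total / (h * w)


class TestMSE:
    def test_identical_images_zero(self, rng):
        img = rng.random((16, 16))
        assert mse(img, img) == 0.0

    def test_sixteen_gray_levels_everywhere(self):
        a = np.zeros((16, 16))
        b = np.full((16, 16), 16 / 255)
        assert mse(a, b) == pytest.approx(256.0)

    def test_matches_per_pixel_loop(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert mse(a, b) == pytest.approx(_loop_mse(a * 255, b * 255),
                                          rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            mse(rng.random((8, 8)), rng.random((8, 9)))


class TestPSNR:
    def test_full_scale_error_is_zero_db(self):
        a = np.zeros((16, 16))
        b = np.ones((16, 16))
        assert psnr(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_thousandth_of_peak_is_thirty_db(self):
        # MSE = 255^2/1000 = 65.025 on the 0-255 scale
        delta = np.sqrt(65.025) / 255.0
        a = np.full((16, 16), 0.4)
        assert psnr(a, a + delta) == pytest.approx(30.0, abs=1e-9)

    def test_identical_images_infinite(self, rng):
        img = rng.random((16, 16))
        assert psnr(img, img) == float("inf")

    def test_strictly_decreasing_in_mse(self, rng):
        a = rng.random((32, 32))
        values = []
        for sigma in (0.01, 0.05, 0.1, 0.2):
            b = np.clip(a + sigma, 0, 1)
            values.append((mse(a, b), psnr(a, b)))
        values.sort()
        psnrs = [p for _, p in values]
        assert all(x > y for x, y in zip(psnrs, psnrs[1:]))


class TestSSIM:
    def test_self_similarity_is_exactly_one(self, rng):
        img = rng.random((32, 32))
        assert ssim(img, img) == 1.0

    def test_inverted_checkerboard_is_negative(self):
        tile = np.indices((32, 32)).sum(axis=0) % 2
        img = tile * 1.0
        assert ssim(img, 1.0 - img) < 0

    def test_symmetric(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ParameterError):
            ssim(rng.random((8, 8)), rng.random((8, 8)))


class TestQMI:
    def test_perfect_fusion_of_identical_sources_scores_two(self, rng):
        img = rng.random((32, 32))
        assert q_mi(img, img, img) == pytest.approx(2.0, abs=1e-12)

    def test_independent_noise_scores_near_zero(self):
        """A fused image independent of both sources carries (almost) no
        mutual information.  The 256-bin histogram estimator has a positive
        finite-sample bias of roughly (bins-1)^2/(2 N ln 2) bits, so "near
        zero" needs enough pixels: at 512x512 the normalized score drops
        below 0.05 and it keeps shrinking as 1/N."""
        g = np.random.default_rng(0)
        small = q_mi(g.random((128, 128)), g.random((128, 128)),
                     g.random((128, 128)))
        a, b = g.random((512, 512)), g.random((512, 512))
        f = g.random((512, 512))
        large = q_mi(a, b, f)
        assert large < 0.05
        assert large < small  # bias shrinks with sample size

    def test_symmetric_in_sources(self, rng):
        a, b, f = (rng.random((32, 32)) for _ in range(3))
        assert q_mi(a, b, f) == pytest.approx(q_mi(b, a, f), abs=1e-12)

    def test_unnormalized_is_mi_sum(self, rng):
        img = rng.random((32, 32))
        # MI(X,X) = H(X); with f == a == b the sum is 2*H(a) > 0
        val = q_mi(img, img, img, normalized=False)
        assert val > 0

    def test_constant_fused_degenerate_under_normalization(self, rng):
        a = rng.random((32, 32))
        f = np.full((32, 32), 0.5)
        with pytest.raises(DegenerateInputError):
            q_mi(a, a, f, normalized=True)


class TestQM:
    def test_self_fusion_scores_one(self, synthetic_pair):
        img = synthetic_pair.composite.pixels
        assert q_m(img, img, img) == pytest.approx(1.0, abs=1e-6)

    def test_constant_fused_destroys_edges(self, synthetic_pair):
        a = synthetic_pair.structural.pixels
        b = synthetic_pair.functional.pixels
        f = np.full_like(a, 0.5)
        assert q_m(a, b, f) < 0.1

    def test_monotone_decreasing_under_blur(self, synthetic_pair):
        a = synthetic_pair.structural.pixels
        b = synthetic_pair.functional.pixels
        f0 = 0.5 * (a + b)
        scores = [q_m(a, b, gaussian_filter(f0, s) if s else f0)
                  for s in (0.0, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(scores, scores[1:]))

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(ParameterError):
            q_m(rng.random((4, 4)), rng.random((4, 4)), rng.random((4, 4)),
                levels=3)


class TestEvaluate:
    def test_report_contains_all_metrics_and_conventions(self, synthetic_pair):
        a = synthetic_pair.structural
        b = synthetic_pair.functional
        f = synthetic_pair.composite
        report = evaluate(a, b, f)
        d = report.to_dict()
        for key in ("mse", "psnr", "ssim", "q_mi", "q_m", "conventions",
                    "mse_a", "psnr_b", "ssim_a"):
            assert key in d
        assert d["mse"] == pytest.approx(0.5 * (d["mse_a"] + d["mse_b"]))
        assert -1 <= d["ssim"] <= 1
        assert 0 <= d["q_m"] <= 1
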