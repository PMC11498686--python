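"""Fusion-quality metric suite: MSE, PSNR, SSIM, Q_MI and Q_M.

All metrics are computed on the 0-255 intensity scale so magnitudes are
commensurate with the image-fusion literature.  Conventions that involve a
choice (PSNR formula, SSIM constants, MI normalization, the Q_M variant)
are recorded in the report's ``conventions`` block.

* MSE — mean squared difference.
* PSNR — ``10 log10(255^2 / MSE)`` dB; identical images give the +infinity
  sentinel.
* SSIM — the canonical structural-similarity index (11x11 Gaussian window,
  sigma 1.5, C1=(0.01 L)^2, C2=(0.03 L)^2, L=255), via scikit-image.
* Q_MI — mutual information of each source with the fused image from
  256-bin joint histograms; the normalized variant (default) divides each
  MI term by the summed marginal entropies and doubles the result, so a
  fused image identical to both sources scores 2.
* Q_M — a multi-scale edge-preservation score: sources and fused image are
  decomposed with the dual-tree complex wavelet transform and, per level
  and orientation, the fused edge magnitude is compared with each source's
  (ratio of the smaller to the larger magnitude), weighted by the source
  edge magnitude and averaged across levels.  This variant is
  implementation-defined — published Q_M columns elsewhere are not directly
  comparable — but it is 1 when edges are perfectly preserved and falls
  toward 0 as they are destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .dualtree import dtcwt_highpass
from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .image import ImagePlane

L_MAX = 255.0


def _arr255(img) -> np.ndarray:
    a = img.pixels if isinstance(img, ImagePlane) else np.asarray(img, float)
    return a * L_MAX


def _check_shapes(*arrs):
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValidationError(
                f"images must share one shape, got {[x.shape for x in arrs]}"
            )


def mse(a, b) -> float:
    """Mean squared error on the 0-255 scale."""
    x, y = _arr255(a), _arr255(b)
    _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(a, b) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    m = mse(a, b)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(L_MAX ** 2 / m))


def ssim(a, b) -> float:
    """Canonical structural similarity (11x11 Gaussian window, sigma 1.5)."""
    x, y = _arr255(a), _arr255(b)
    _check_shapes(x, y)
    if min(x.shape) < 11:
        raise ParameterError("images must be at least 11x11 for SSIM")
    if np.array_equal(x, y):
        return 1.0
    return float(structural_similarity(
        x, y, data_range=L_MAX, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False,
    ))


def _entropy_and_mi(x255: np.ndarray, y255: np.ndarray, bins: int = 256):
    """Marginal entropies and mutual information in bits (256-bin hists)."""
    ix = np.clip(np.round(x255), 0, bins - 1).astype(int)
    iy = np.clip(np.round(y255), 0, bins - 1).astype(int)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ix.ravel(), iy.ravel()), 1.0)
    p = joint / joint.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)

    def _h(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum() / np.log(2))

    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / np.outer(px, py)[nz])).sum() / np.log(2))
    return _h(px), _h(py), mi


def q_mi(a, b, f, normalized: bool = True) -> float:
    """Mutual-information fusion quality.

    ``normalized=False``: MI(A,F) + MI(B,F).
    ``normalized=True`` (default): 2 * [MI(A,F)/(H(A)+H(F))
    + MI(B,F)/(H(B)+H(F))].
    """
    xa, xb, xf = _arr255(a), _arr255(b), _arr255(f)
    _check_shapes(xa, xb, xf)
    ha, hf, mi_af = _entropy_and_mi(xa, xf)
    hb, hf2, mi_bf = _entropy_and_mi(xb, xf)
    if not normalized:
        return mi_af + mi_bf
    if hf == 0.0:
        raise DegenerateInputError(
            "fused image has zero entropy (constant); the normalized Q_MI "
            "denominator degenerates"
        )
    return 2.0 * (mi_af / (ha + hf) + mi_bf / (hb + hf2))


def q_m(a, b, f, levels: int = 3) -> float:
    """Multi-scale edge-preservation score in [0, 1] (see module docstring)."""
    xa = _arr255(a) / L_MAX
    xb = _arr255(b) / L_MAX
    xf = _arr255(f) / L_MAX
    _check_shapes(xa, xb, xf)
    if min(xa.shape) < 2 ** levels:
        raise ParameterError(
            f"images too small for {levels} decomposition levels"
        )
    ha = dtcwt_highpass(xa, levels)
    hb = dtcwt_highpass(xb, levels)
    hf = dtcwt_highpass(xf, levels)
    scores = []
    for la, lb, lf in zip(ha, hb, hf):
        ma, mb, mf = np.abs(la), np.abs(lb), np.abs(lf)
        num = 0.0
        den = 0.0
        for ms in (ma, mb):
            hi = np.maximum(ms, mf)
            pres = np.where(hi > 0, np.minimum(ms, mf) / np.where(hi > 0, hi, 1.0), 1.0)
            num += float((pres * ms).sum())
            den += float(ms.sum())
        scores.append(num / den if den > 0 else 1.0)
    return float(np.mean(scores))


CONVENTIONS = {
    "scale": "0-255",
    "psnr": "10*log10(255^2/MSE), +inf sentinel at MSE=0",
    "ssim": "canonical formulation, 11x11 Gaussian window sigma=1.5, "
            "C1=(0.01*255)^2, C2=(0.03*255)^2",
    "q_mi": "256-bin joint histograms, entropies in bits; normalized "
            "variant 2*[MI(A,F)/(H(A)+H(F)) + MI(B,F)/(H(B)+H(F))]",
    "q_m": "implementation-defined multi-scale edge preservation over "
           "dual-tree complex wavelet subbands (not comparable across "
           "implementations)",
    "mse_psnr_aggregation": "reported per source and as the mean",
}


@dataclass
class MetricReport:
    """All five metrics for one fused image against its two sources."""

    mse: float
    psnr: float
    ssim: float
    q_mi: float
    q_m: float
    per_source: dict = field(default_factory=dict)
    conventions: dict = field(default_factory=lambda: dict(CONVENTIONS))

    def to_dict(self) -> dict:
        d = {
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "q_mi": self.q_mi,
            "q_m": self.q_m,
        }
        d.update({f"{k}": v for k, v in self.per_source.items()})
        d["conventions"] = dict(self.conventions)
        return d


def evaluate(a, b, f, normalized_qmi: bool = True,
             qm_levels: int = 3) -> MetricReport:
    """Compute the full metric suite for fused image ``f`` against sources
    ``a`` and ``b``; MSE/PSNR/SSIM are reported per source and as means."""
    per = {
        "mse_a": mse(a, f), "mse_b": mse(b, f),
        "psnr_a": psnr(a, f), "psnr_b": psnr(b, f),
        "ssim_a": ssim(a, f), "ssim_b": ssim(b, f),
    }
    return MetricReport(
        mse=0.5 * (per["mse_a"] + per["mse_b"]),
        psnr=0.5 * (per["psnr_a"] + per["psnr_b"]),
        ssim=0.5 * (per["ssim_a"] + per["ssim_b"]),
        q_mi=q_mi(a, b, f, normalized=normalized_qmi),
        q_m=q_m(a, b, f, levels=qm_levels),
        per_source=per,
    )
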