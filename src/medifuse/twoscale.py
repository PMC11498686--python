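"""Two-scale base/detail decomposition of a source image.

The default method solves the quadratic problem

    I_b = argmin ||I - I_b||_F^2 + lam * (||g_x * I_b||_F^2 + ||g_y * I_b||_F^2)

with first-difference gradient operators g_x = [-1 1], g_y = [-1 1]^T and
periodic convolution.  The normal equations are diagonalized by the 2-D DFT,
so the unique minimizer is computed exactly in the frequency domain:

    I_b = F^-1[ F(I) / (1 + lam * (|F(g_x)|^2 + |F(g_y)|^2)) ]

The detail part is the residual, ``I_d = I - I_b``, so base + detail always
reconstructs the input.  ``lam`` trades smoothness of the base against how
much content is pushed into the detail layer: lam -> 0 keeps everything in
the base, lam -> infinity drives the base to the image mean.

A dual-tree complex wavelet decomposition is available as an alternative
backend (``decompose_dtcwt``): the base is the deepest-level lowpass put
back through the synthesis chain with all highpass subbands zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dualtree import dtcwt_base
from .exceptions import ParameterError
from .image import ImagePlane

DEFAULT_LAMBDA = 5.0
DEFAULT_LEVELS = 2


@dataclass
class TwoScaleDecomposition:
    """Base part and detail content of one source image.

    ``base + detail`` equals the input to double precision; detail values may
    be negative.
    """

    base: np.ndarray
    detail: np.ndarray
    method: str
    lam: Optional[float] = None
    levels: Optional[int] = None

    def reconstruct(self) -> np.ndarray:
        return self.base + self.detail


def _as_array(img) -> np.ndarray:
    if isinstance(img, ImagePlane):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def gradient_otf(shape) -> np.ndarray:
    """|F(g_x)|^2 + |F(g_y)|^2 on the given grid (periodic convolution)."""
    h, w = shape
    # first differences: |1 - exp(-j*omega)|^2 = 2 - 2 cos(omega)
    wx = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(w) / w)
    wy = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(h) / h)
    return wy[:, None] + wx[None, :]


def decompose_optimization(img, lam: float = DEFAULT_LAMBDA) -> TwoScaleDecomposition:
    """Split an image into base + detail via the quadratic smoothing problem."""
    if lam <= 0:
        raise ParameterError(f"lam must be positive, got {lam}")
    arr = _as_array(img)
    denom = 1.0 + lam * gradient_otf(arr.shape)
    base = np.fft.ifft2(np.fft.fft2(arr) / denom).real
    return TwoScaleDecomposition(base=base, detail=arr - base,
                                 method="optimization", lam=lam)


def decompose_dtcwt(img, levels: int = DEFAULT_LEVELS) -> TwoScaleDecomposition:
    """Split an image into base + detail with the dual-tree wavelet backend.

    The detail is defined as the residual ``img - base`` so additivity holds
    by construction.
    """
    arr = _as_array(img)
    base = dtcwt_base(arr, levels)  # validates levels against image size
    return TwoScaleDecomposition(base=base, detail=arr - base,
                                 method="dtcwt", levels=levels)


def decompose(img, method: str = "optimization", lam: float = DEFAULT_LAMBDA,
              levels: int = DEFAULT_LEVELS) -> TwoScaleDecomposition:
    """Dispatch on the decomposition method name."""
    if method == "optimization":
        return decompose_optimization(img, lam=lam)
    if method == "dtcwt":
        return decompose_dtcwt(img, levels=levels)
    raise ParameterError(f"unknown decomposition method {method!r}")
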