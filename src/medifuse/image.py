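"""Image I/O, canonicalization and optional preprocessing.

The whole pipeline works on a single canonical currency: :class:`ImagePlane`,
a single-channel float64 image with intensities in [0, 1].  Color inputs
(e.g. pseudo-colored PET) are reduced to Rec.601 luminance on read; the
original RGB data is kept in ``meta["color"]`` so chroma can be re-injected
after fusion.

Preprocessing — rigid registration against an SSD or mutual-information
cost, Perona–Malik anisotropic diffusion, and classical histogram
equalization — is provided here but is *off by default*: fusion assumes
pre-registered sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage, optimize

from .exceptions import (
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

#: Rec.601 luma weights for R, G, B.
REC601 = np.array([0.299, 0.587, 0.114])

MIN_SIDE = 16  # minimum side so at least one 16x16 patch fits


@dataclass
class ImagePlane:
    """A single-channel real-valued image with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array; values must lie in [0, 1].
    source_bit_depth
        Bit depth of the file the plane came from (8 or 16); synthetic
        planes default to 8.
    meta
        Free-form provenance tags.  ``meta["color"]`` holds the original
        RGB float array (in [0, 1]) when the source was color.
    """

    pixels: np.ndarray
    source_bit_depth: int = 8
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"ImagePlane expects a 2-D array, got ndim={self.pixels.ndim}"
            )
        h, w = self.pixels.shape
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValidationError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {h}x{w}"
            )
        if self.source_bit_depth not in (8, 16):
            raise ParameterError("source_bit_depth must be 8 or 16")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValidationError(
                f"pixel values must lie in [0, 1], got range [{lo}, {hi}]"
            )
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class RigidTransform:
    """A rigid (translation + rotation) transform with its registration cost."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0  # degrees
    cost_name: str = "ssd"
    cost_value: float = 0.0


def _to_array(img) -> np.ndarray:
    return img.pixels if isinstance(img, ImagePlane) else np.asarray(img, float)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path) -> ImagePlane:
    """Read a PNG/TIFF/JPEG image into a canonical luminance plane.

    Integer intensities are divided by ``2**bit_depth - 1``; color inputs are
    reduced with Rec.601 weights (0.299, 0.587, 0.114) and the normalized RGB
    kept in ``meta["color"]``.
    """
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio plugins raise a mix of error types
        raise FormatError(
            f"could not read image file {str(path)!r}: {exc}"
        ) from exc
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {path!r}")

    if raw.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif raw.dtype == np.uint16:
        depth, scale = 16, 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        depth, scale = 8, 1.0
    else:
        raise FormatError(f"unsupported pixel dtype {raw.dtype} in {path!r}")

    data = np.asarray(raw, dtype=np.float64) / scale
    meta = {"path": str(path)}
    if data.ndim == 3:
        if data.shape[2] == 4:  # drop alpha
            data = data[:, :, :3]
        if data.shape[2] != 3:
            raise FormatError(
                f"unsupported channel count {data.shape[2]} in {path!r}"
            )
        meta["color"] = data.copy()
        data = data @ REC601
    elif data.ndim != 2:
        raise FormatError(f"unsupported image dimensionality in {path!r}")
    data = np.clip(data, 0.0, 1.0)
    return ImagePlane(pixels=data, source_bit_depth=depth, meta=meta)


def quantize(pixels: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Quantize [0, 1] floats to unsigned integers, round half to even."""
    if bit_depth == 8:
        return np.round(np.clip(pixels, 0, 1) * 255.0).astype(np.uint8)
    if bit_depth == 16:
        return np.round(np.clip(pixels, 0, 1) * 65535.0).astype(np.uint16)
    raise ParameterError("bit_depth must be 8 or 16")


def write_image(path, img, bit_depth: int = 8) -> None:
    """Write an ImagePlane (or array in [0,1]) as an 8- or 16-bit image."""
    arr = _to_array(img)
    iio.imwrite(path, quantize(arr, bit_depth))


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def apply_rigid(img, dx: float, dy: float, theta: float) -> np.ndarray:
    """Move image content by (dx, dy) pixels after rotating ``theta`` degrees
    about the image center.  Bilinear resampling, zero fill outside the frame.

    The identity transform returns the input bit-identically.
    """
    arr = _to_array(img)
    if dx == 0.0 and dy == 0.0 and theta == 0.0:
        return arr.copy()
    ang = np.deg2rad(theta)
    c, s = np.cos(ang), np.sin(ang)
    center = (np.asarray(arr.shape, float) - 1.0) / 2.0
    # output coords -> input coords: rotate by -theta about center, then -t
    rot = np.array([[c, s], [-s, c]])
    offset = center - rot @ (center + np.array([dx, dy]))
    return ndimage.affine_transform(
        arr, rot, offset=offset, order=1, mode="constant", cval=0.0,
        prefilter=False,
    )


def ssd_cost(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of squared differences over the full frame."""
    d = a - b
    return float(np.sum(d * d))


def mi_cost(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Mutual information from a Laplace-smoothed joint histogram (bits)."""
    ia = np.clip((a * (bins - 1)).round().astype(int), 0, bins - 1)
    ib = np.clip((b * (bins - 1)).round().astype(int), 0, bins - 1)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ia.ravel(), ib.ravel()), 1.0)
    joint += 1.0  # Laplace smoothing: no log 0
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    return float(np.sum(p * np.log2(p / (px * py))))


@dataclass
class SearchBounds:
    """Grid bounds for the coarse registration search."""

    max_shift: int = 5          # +/- pixels, integer grid
    max_angle: float = 0.0      # +/- degrees
    angle_step: float = 1.0


def register_rigid(
    moving,
    fixed,
    cost: str = "ssd",
    search: Optional[SearchBounds] = None,
) -> tuple:
    """Rigidly align ``moving`` to ``fixed``.

    Coarse exhaustive search on an integer translation grid crossed with a
    coarse angle grid, followed by Powell refinement of (dx, dy, theta).
    The objective is evaluated over the overlap region only (mean SSD
    minimized, or MI maximized), so frame borders exposed by the transform
    do not bias the optimum.  Returns the resampled moving image and the
    :class:`RigidTransform` found, with the cost of the returned transform.
    """
    mov, fix = _to_array(moving), _to_array(fixed)
    if mov.shape != fix.shape:
        raise ValidationError(
            f"moving {mov.shape} and fixed {fix.shape} must share a shape"
        )
    if cost not in ("ssd", "mi"):
        raise ParameterError(f"cost must be 'ssd' or 'mi', got {cost!r}")
    if cost == "mi" and fix.max() - fix.min() < 1e-12:
        raise DegenerateInputError(
            "fixed image is constant: mutual information is undefined up to ties"
        )
    search = search or SearchBounds()
    if not np.isfinite([search.max_shift, search.max_angle]).all():
        raise ParameterError("search bounds must be finite")

    sign = 1.0 if cost == "ssd" else -1.0

    def masked_cost(resampled, valid):
        """Cost over the overlap region only: zero-filled pixels carried in
        from outside the frame would otherwise penalize the true transform
        more than a one-pixel misalignment does."""
        if valid.mean() < 0.25:
            return np.inf
        if cost == "ssd":
            d = resampled[valid] - fix[valid]
            return float(np.mean(d * d))
        return mi_cost(resampled[valid], fix[valid])

    support = np.ones_like(mov)

    def objective(params):
        dx, dy, th = params
        resampled = apply_rigid(mov, dx, dy, th)
        valid = apply_rigid(support, dx, dy, th) > 0.999
        return sign * masked_cost(resampled, valid)

    shifts = range(-search.max_shift, search.max_shift + 1)
    if search.max_angle > 0:
        angles = np.arange(-search.max_angle, search.max_angle + 1e-9,
                           search.angle_step)
    else:
        angles = np.array([0.0])

    best, best_val = (0.0, 0.0, 0.0), np.inf
    for th in angles:
        for dx in shifts:
            for dy in shifts:
                v = objective((dx, dy, th))
                if v < best_val:
                    best_val, best = v, (float(dx), float(dy), float(th))

    lo = [best[0] - 1, best[1] - 1, best[2] - search.angle_step]
    hi = [best[0] + 1, best[1] + 1, best[2] + search.angle_step]
    res = optimize.minimize(
        objective, np.asarray(best), method="Powell",
        bounds=list(zip(lo, hi)),
        options={"xtol": 1e-3, "ftol": 1e-6},
    )
    params = res.x if res.fun <= best_val else np.asarray(best)
    dx, dy, th = (float(p) for p in params)
    resampled = apply_rigid(mov, dx, dy, th)
    final_valid = apply_rigid(support, dx, dy, th) > 0.999
    final_cost = masked_cost(resampled, final_valid)
    out = ImagePlane(np.clip(resampled, 0, 1),
                     meta={"registered": True, "cost": cost})
    return out, RigidTransform(dx=dx, dy=dy, theta=th,
                               cost_name=cost, cost_value=final_cost)


# ---------------------------------------------------------------------------
# Enhancement
# ---------------------------------------------------------------------------

def anisodiffuse(img, iterations: int = 10, kappa: float = 0.1,
                 dt: float = 0.2):
    """Perona–Malik anisotropic diffusion with exponential conductance.

    ``g(grad) = exp(-(grad/kappa)^2)``, 4-neighbor explicit scheme, Neumann
    (replicated) borders.  ``iterations=0`` returns the input unchanged.
    """
    if iterations < 0:
        raise ParameterError("iterations must be >= 0")
    if kappa <= 0:
        raise ParameterError("kappa must be positive")
    if not 0 < dt <= 0.25:
        raise ParameterError("dt must lie in (0, 0.25]")
    arr = _to_array(img).copy()
    for _ in range(int(iterations)):
        # neighbor differences with Neumann borders (zero flux at the edge)
        dn = np.zeros_like(arr); dn[1:, :] = arr[:-1, :] - arr[1:, :]
        ds = np.zeros_like(arr); ds[:-1, :] = arr[1:, :] - arr[:-1, :]
        de = np.zeros_like(arr); de[:, :-1] = arr[:, 1:] - arr[:, :-1]
        dw = np.zeros_like(arr); dw[:, 1:] = arr[:, :-1] - arr[:, 1:]
        flux = sum(np.exp(-(d / kappa) ** 2) * d for d in (dn, ds, de, dw))
        arr += dt * flux
    out = np.clip(arr, 0.0, 1.0)
    if isinstance(img, ImagePlane):
        return ImagePlane(out, img.source_bit_depth, dict(img.meta))
    return out


def hist_equalize(img):
    """Classical CDF-mapping histogram equalization on 256 bins.

    Each 8-bit level maps to its cumulative probability, so the output
    occupies [0, 1].  A constant image is returned unchanged.
    """
    arr = _to_array(img)
    levels = np.clip(np.round(arr * 255.0).astype(int), 0, 255)
    if levels.min() == levels.max():
        out = arr.copy()
    else:
        hist = np.bincount(levels.ravel(), minlength=256)
        cdf = np.cumsum(hist) / levels.size
        out = cdf[levels]
    if isinstance(img, ImagePlane):
        return ImagePlane(out, img.source_bit_depth, dict(img.meta))
    return out
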