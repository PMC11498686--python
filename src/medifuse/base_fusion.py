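"""Base-part fusion.

The two base parts are blended by a weighted sum,

    F_b(x, y) = a1 * I_1^b(x, y) + a2 * I_2^b(x, y),

either with fixed scalars (default a1 = a2 = 0.5, which preserves the
features common to both sources) or with a per-pixel weight map W in [0, 1]
produced by the Siamese saliency network:

    F_b = W . I_1^b + (1 - W) . I_2^b

Both forms are convex combinations, so the fused base stays pointwise
between the two inputs and inside [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ParameterError, ValidationError
from .image import ImagePlane


@dataclass
class BaseFusionConfig:
    mode: str = "scalar"          # "scalar" | "snn"
    alpha1: float = 0.5
    alpha2: float = 0.5
    weight_map: Optional[np.ndarray] = None

    def validate(self, shape) -> None:
        if self.mode == "scalar":
            if not (0 <= self.alpha1 <= 1 and 0 <= self.alpha2 <= 1):
                raise ParameterError("alpha1 and alpha2 must lie in [0, 1]")
            if abs(self.alpha1 + self.alpha2 - 1.0) > 1e-9:
                raise ParameterError(
                    f"alpha1 + alpha2 must equal 1, got "
                    f"{self.alpha1 + self.alpha2}"
                )
        elif self.mode == "snn":
            if self.weight_map is None:
                raise ParameterError("snn mode requires a weight_map")
            w = np.asarray(self.weight_map)
            if w.shape != tuple(shape):
                raise ValidationError(
                    f"weight map shape {w.shape} does not match bases {shape}"
                )
            if w.min() < 0 or w.max() > 1:
                raise ValidationError("weight map entries must lie in [0, 1]")
        else:
            raise ParameterError(f"unknown base fusion mode {self.mode!r}")


def _arr(img):
    return img.pixels if isinstance(img, ImagePlane) else np.asarray(img, float)


def fuse_base(base1, base2, cfg: Optional[BaseFusionConfig] = None) -> np.ndarray:
    """Weighted-sum fusion of two base parts (see module docstring)."""
    b1, b2 = _arr(base1), _arr(base2)
    if b1.shape != b2.shape:
        raise ValidationError(
            f"base parts must share a shape, got {b1.shape} vs {b2.shape}"
        )
    cfg = cfg or BaseFusionConfig()
    cfg.validate(b1.shape)
    if cfg.mode == "scalar":
        return cfg.alpha1 * b1 + cfg.alpha2 * b2
    w = np.asarray(cfg.weight_map, float)
    return w * b1 + (1.0 - w) * b2
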