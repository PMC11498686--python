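"""Multi-layer deep-feature extraction for the detail-fusion branch.

The detail branch needs, for each source's detail content, four levels of
rectified feature maps with a fixed channel/stride schedule: level i has
``64 * 2**(i-1)`` channels at ``ceil(H / 2**(i-1)) x ceil(W / 2**(i-1))``
pixels — the shapes produced by the first ReLU of each of the first four
convolution blocks of VGG-19 (relu1_1, relu2_1, relu3_1, relu4_1).

Two extractors satisfy that contract:

* :func:`make_fixture_extractor` — a seeded, bias-free random convolution
  bank (3x3 kernels, ReLU, stride-2 average pooling between stages).  It is
  fully deterministic, needs no downloads, and is the default.
* :func:`make_vgg19_extractor` — a forward pass over pretrained VGG-19
  convolution weights supplied by the user as an ``.npz`` file.  Nothing is
  downloaded implicitly.

Any object with an ``extractor_id`` attribute and a ``__call__`` taking a
2-D detail array and returning four ``(C, H, W)`` arrays can be plugged in;
:func:`extract_features` validates the contract at run time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, List, Sequence

import numpy as np

from .exceptions import ContractViolationError, ParameterError

CHANNELS = (64, 128, 256, 512)

#: ImageNet channel statistics used to normalize input to the VGG adapter.
_VGG_MEAN = np.array([0.485, 0.456, 0.406])
_VGG_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class FeatureStack:
    """Per-source deep feature maps at four levels."""

    levels: List[np.ndarray]  # four (C, H, W) arrays
    extractor_id: str

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ContractViolationError(
                f"FeatureStack needs exactly 4 levels, got {len(self.levels)}"
            )


def level_shape(input_shape, i: int):
    """Spatial size of feature level ``i`` (1-based) for a given input."""
    f = 2 ** (i - 1)
    return (-(-input_shape[0] // f), -(-input_shape[1] // f))


def validate_feature_stack(stack: FeatureStack, input_shape) -> None:
    """Check the channel/stride schedule and non-negativity of a stack."""
    for i, lvl in enumerate(stack.levels, start=1):
        if lvl.ndim != 3 or lvl.shape[0] != CHANNELS[i - 1]:
            raise ContractViolationError(
                f"level {i}: expected {CHANNELS[i - 1]} channels, "
                f"got shape {lvl.shape}"
            )
        expect = level_shape(input_shape, i)
        if lvl.shape[1:] != expect:
            raise ContractViolationError(
                f"level {i}: expected spatial size {expect}, got {lvl.shape[1:]}"
            )
        if lvl.size and lvl.min() < 0:
            raise ContractViolationError(
                f"level {i}: feature maps must be non-negative (rectified)"
            )


def extract_features(detail: np.ndarray, extractor) -> FeatureStack:
    """Run an extractor on one detail image and validate its output."""
    detail = np.asarray(detail, dtype=np.float64)
    if detail.ndim != 2:
        raise ParameterError("detail must be a single-channel 2-D array")
    levels = extractor(detail)
    stack = FeatureStack(levels=[np.asarray(l) for l in levels],
                         extractor_id=getattr(extractor, "extractor_id",
                                              type(extractor).__name__))
    validate_feature_stack(stack, detail.shape)
    return stack


# ---------------------------------------------------------------------------
# shared conv machinery (im2col + GEMM)
# ---------------------------------------------------------------------------

def conv3x3(x: np.ndarray, weight: np.ndarray,
            bias: np.ndarray | None = None) -> np.ndarray:
    """3x3 same-size convolution of a (C, H, W) stack.

    Borders are edge-replicated so a spatially constant input stays
    spatially constant through every stage.
    """
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)), mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)
    out = cols @ weight.reshape(weight.shape[0], -1).T
    if bias is not None:
        out += bias
    return out.T.reshape(weight.shape[0], h, w)


def _pool2(x: np.ndarray, op) -> np.ndarray:
    """2x2 stride-2 pooling with ceil semantics (edge-replicated padding)."""
    c, h, w = x.shape
    if h % 2 or w % 2:
        x = np.pad(x, ((0, 0), (0, h % 2), (0, w % 2)), mode="edge")
        h, w = x.shape[1:]
    blocks = x.reshape(c, h // 2, 2, w // 2, 2)
    return op(blocks, axis=(2, 4))


def avg_pool2(x):
    return _pool2(x, np.mean)


def max_pool2(x):
    return _pool2(x, np.max)


# ---------------------------------------------------------------------------
# fixture extractor
# ---------------------------------------------------------------------------

class FixtureExtractor:
    """Seeded random convolution bank satisfying the feature contract.

    Four stages of bias-free 3x3 convolution + ReLU with channel counts
    (64, 128, 256, 512) and stride-2 average pooling between stages.  Zero
    input maps to zero output at every level, and the same seed always
    produces bit-identical kernels and features.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.extractor_id = f"fixture(seed={self.seed})"
        rng = np.random.default_rng(self.seed)
        self.kernels = []
        in_ch = 1
        for out_ch in CHANNELS:
            scale = np.sqrt(2.0 / (in_ch * 9))
            self.kernels.append(
                rng.standard_normal((out_ch, in_ch, 3, 3)) * scale
            )
            in_ch = out_ch

    def __call__(self, detail: np.ndarray) -> List[np.ndarray]:
        x = np.asarray(detail, float)[None, :, :]
        levels = []
        for i, k in enumerate(self.kernels):
            x = np.maximum(conv3x3(x, k), 0.0)
            levels.append(x)
            if i < 3:
                x = avg_pool2(x)
        return levels


def make_fixture_extractor(seed: int) -> FixtureExtractor:
    """Build the deterministic download-free fixture extractor."""
    return FixtureExtractor(seed)


# ---------------------------------------------------------------------------
# VGG-19 adapter
# ---------------------------------------------------------------------------

#: conv layers of VGG-19 up to conv4_1, with the levels we tap.
_VGG_PLAN = [
    ("conv1_1", True),   # -> relu1_1 (level 1)
    ("conv1_2", False),
    ("pool", None),
    ("conv2_1", True),   # -> relu2_1 (level 2)
    ("conv2_2", False),
    ("pool", None),
    ("conv3_1", True),   # -> relu3_1 (level 3)
    ("conv3_2", False),
    ("conv3_3", False),
    ("conv3_4", False),
    ("pool", None),
    ("conv4_1", True),   # -> relu4_1 (level 4)
]


class VGG19Extractor:
    """NumPy forward pass over pretrained VGG-19 convolution weights.

    ``weights`` maps layer names (``conv1_1`` ... ``conv4_1``) to
    ``(weight, bias)`` pairs with torch-layout weights ``(out, in, 3, 3)``.
    Grayscale detail input is shifted to [0, 1] around mid-gray, replicated
    to three channels and normalized with the ImageNet mean/std convention.
    """

    def __init__(self, weights: dict, source: str = "npz"):
        self.weights = weights
        self.extractor_id = f"vgg19({source})"

    def __call__(self, detail: np.ndarray) -> List[np.ndarray]:
        x = np.clip(np.asarray(detail, float) + 0.5, 0.0, 1.0)
        x = np.repeat(x[None, :, :], 3, axis=0)
        x = (x - _VGG_MEAN[:, None, None]) / _VGG_STD[:, None, None]
        levels = []
        for name, tap in _VGG_PLAN:
            if name == "pool":
                x = max_pool2(x)
                continue
            w, b = self.weights[name]
            x = np.maximum(conv3x3(x, w, b), 0.0)
            if tap:
                levels.append(x)
        return levels


def make_vgg19_extractor(weights_path: str) -> VGG19Extractor:
    """Load pretrained VGG-19 conv weights from an ``.npz`` file.

    The archive must contain ``<layer>.weight`` and ``<layer>.bias`` arrays
    for conv1_1 ... conv4_1.  If the file is missing, the error points the
    user at the fixture extractor, which needs no weights.
    """
    if not weights_path or not os.path.exists(weights_path):
        raise ParameterError(
            f"VGG-19 weights not found at {weights_path!r}. Export the "
            "pretrained convolution weights to an .npz file (keys like "
            "'conv1_1.weight'), or use the fixture extractor "
            "(make_fixture_extractor(seed)), which requires no weights."
        )
    with np.load(weights_path) as npz:
        weights = {}
        for name, _ in _VGG_PLAN:
            if name == "pool":
                continue
            try:
                weights[name] = (npz[f"{name}.weight"].astype(float),
                                 npz[f"{name}.bias"].astype(float))
            except KeyError as exc:
                raise ParameterError(
                    f"weights file {weights_path!r} lacks arrays for "
                    f"layer {name}"
                ) from exc
    return VGG19Extractor(weights, source=os.path.basename(weights_path))
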