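"""Detail-content fusion from multi-layer deep features.

For each source k and feature level i the branch computes:

1. an *initial activity map* ``C_k^i(x,y)`` — the L1 norm across feature
   channels at each position (how strongly the detail content activates the
   extractor there);
2. a *final activity map* — a block average over a (2r+1) x (2r+1) window
   (out-of-frame terms contribute zero), which makes the fusion robust to
   slight misregistration; r = 1 by default;
3. *softmax weights* across the K sources, ``w_k = c_k / sum_n c_n``
   (uniform 1/K where every activity is zero);
4. *block-replication upsampling* of the level-i weight map back to detail
   resolution: each weight fills its ``2**(i-1) x 2**(i-1)`` block, cropped
   to the target size, which preserves the per-pixel sum-to-1 exactly;
5. a per-level fused detail ``F_d^i = sum_k w_k^i * I_k^d`` and finally the
   pointwise maximum across the four levels, ``F_d = max_i F_d^i``.

The maximum is taken on signed values: detail coefficients may be negative
and no absolute value is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .exceptions import ParameterError, ValidationError
from .features import FeatureStack

DEFAULT_BLOCK_RADIUS = 1


@dataclass
class ActivityMap:
    """Initial (L1-norm) and final (block-averaged) activity of one source."""

    initial: np.ndarray
    final: np.ndarray
    level: int
    r: int


@dataclass
class WeightMap:
    """Per-source pixel weights in [0, 1] summing to 1 across sources."""

    per_source: List[np.ndarray]
    level: int
    upsampled: bool = False


@dataclass
class DetailFusionResult:
    """Per-level fused details and their pointwise maximum."""

    per_level: List[np.ndarray]
    combined: np.ndarray


def activity_map(features: np.ndarray) -> np.ndarray:
    """L1 norm across channels of one (C, H, W) feature level."""
    features = np.asarray(features)
    if features.ndim != 3 or features.shape[0] == 0:
        raise ParameterError("expected a non-empty (C, H, W) feature level")
    return np.abs(features).sum(axis=0)


def block_average(initial: np.ndarray, r: int = DEFAULT_BLOCK_RADIUS) -> np.ndarray:
    """Average over a (2r+1)x(2r+1) window; out-of-frame terms are zero,
    and the divisor stays (2r+1)^2 everywhere (no border renormalization)."""
    if r < 0:
        raise ParameterError("block radius r must be >= 0")
    if r == 0:
        return np.asarray(initial, float).copy()
    size = 2 * r + 1
    padded = np.pad(np.asarray(initial, float), r)
    win = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    return win.sum(axis=(-2, -1)) / (size * size)


def softmax_weights(finals: Sequence[np.ndarray]) -> List[np.ndarray]:
    """Normalize K activity maps to per-pixel weights summing to one.

    Where the total activity is zero each source receives 1/K.
    """
    finals = [np.asarray(f, float) for f in finals]
    shape = finals[0].shape
    for f in finals:
        if f.shape != shape:
            raise ValidationError("activity maps must share one shape")
        if f.size and f.min() < 0:
            raise ValidationError("activity maps must be non-negative")
    k = len(finals)
    total = np.sum(finals, axis=0)
    zero = total == 0
    safe = np.where(zero, 1.0, total)
    if k == 2:
        # compute the dominant source's weight (>= 0.5) by division and the
        # other as its complement: the complement is exact for values in
        # [0.5, 1], so the pair sums to exactly 1 *and* swapping the inputs
        # swaps the weights bit-identically
        c1, c2 = finals
        wmax = np.where(zero, 0.5, np.maximum(c1, c2) / safe)
        wmin = 1.0 - wmax
        first_dominates = c1 >= c2
        return [np.where(first_dominates, wmax, wmin),
                np.where(first_dominates, wmin, wmax)]
    return [np.where(zero, 1.0 / k, f / safe) for f in finals]


def upsample_weights(w: np.ndarray, target, level: int) -> np.ndarray:
    """Replicate each level-``level`` weight over its 2**(level-1) block and
    crop to the target shape (exact nearest-neighbor block replication)."""
    w = np.asarray(w, float)
    f = 2 ** (level - 1)
    th, tw = target
    if (-(-th // f), -(-tw // f)) != w.shape:
        raise ParameterError(
            f"target {target} incompatible with level-{level} map {w.shape}"
        )
    up = np.repeat(np.repeat(w, f, axis=0), f, axis=1)
    return up[:th, :tw]


def fuse_detail_contents(
    details: Sequence[np.ndarray],
    weight_maps: Sequence[Sequence[np.ndarray]],
) -> DetailFusionResult:
    """Blend K detail images with four full-resolution weight-map sets and
    take the pointwise maximum across levels.

    ``weight_maps[i][k]`` is the upsampled weight of source ``k`` at level
    ``i``; every array must share the detail shape.
    """
    details = [np.asarray(d, float) for d in details]
    shape = details[0].shape
    for d in details:
        if d.shape != shape:
            raise ValidationError("detail images must share one shape")
    per_level = []
    for maps in weight_maps:
        if len(maps) != len(details):
            raise ValidationError("one weight map per source is required")
        fused = np.zeros(shape)
        for wk, dk in zip(maps, details):
            wk = np.asarray(wk, float)
            if wk.shape != shape:
                raise ValidationError(
                    "weight maps must be upsampled to the detail shape"
                )
            fused += wk * dk
        per_level.append(fused)
    combined = np.maximum.reduce(per_level)
    return DetailFusionResult(per_level=per_level, combined=combined)


def fuse_details(
    details: Sequence[np.ndarray],
    stacks: Sequence[FeatureStack],
    r: int = DEFAULT_BLOCK_RADIUS,
) -> DetailFusionResult:
    """Run the whole detail branch for K sources.

    ``stacks[k]`` holds the four feature levels of ``details[k]``.
    """
    if len(details) != len(stacks):
        raise ValidationError("one feature stack per detail image is required")
    shape = np.asarray(details[0]).shape
    weight_maps = []
    for i in range(1, 5):
        finals = [
            block_average(activity_map(stack.levels[i - 1]), r)
            for stack in stacks
        ]
        level_weights = softmax_weights(finals)
        weight_maps.append(
            [upsample_weights(w, shape, i) for w in level_weights]
        )
    return fuse_detail_contents(details, weight_maps)
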