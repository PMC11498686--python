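"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive — dense matrices, per-pixel loops —
and shares no code with the implementation it checks.
"""

import numpy as np


def periodic_difference_matrix(n: int) -> np.ndarray:
    """Dense circulant first-difference operator: (Dx)_i = x_{i+1} - x_i."""
    d = -np.eye(n)
    d += np.roll(np.eye(n), -1, axis=1)
    return d


def dense_base_solve(img: np.ndarray, lam: float) -> np.ndarray:
    """Solve (I + lam*(Gx^T Gx + Gy^T Gy)) vec(b) = vec(img) densely,
    with periodic difference operators along each axis."""
    h, w = img.shape
    dy = periodic_difference_matrix(h)
    dx = periodic_difference_matrix(w)
    gy = np.kron(np.eye(w), dy)          # vec in column-major (Fortran) order
    gx = np.kron(dx, np.eye(h))
    a = np.eye(h * w) + lam * (gy.T @ gy + gx.T @ gx)
    b = np.linalg.solve(a, img.reshape(-1, order="F"))
    return b.reshape(h, w, order="F")


def loop_activity_map(level: np.ndarray) -> np.ndarray:
    """Per-pixel loop over channels summing absolute values."""
    c, h, w = level.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            s = 0.0
            for n in range(c):
                s += abs(level[n, y, x])
            out[y, x] = s
    return out


def loop_block_average(cmap: np.ndarray, r: int) -> np.ndarray:
    """Window sums with zero out-of-frame terms, divisor (2r+1)^2."""
    h, w = cmap.shape
    out = np.zeros((h, w))
    size = (2 * r + 1) ** 2
    padded = np.pad(cmap, r)
    for y in range(h):
        for x in range(w):
            out[y, x] = np.sum(padded[y:y + 2 * r + 1, x:x + 2 * r + 1]) / size
    return out


def loop_upsample(w: np.ndarray, target, level: int) -> np.ndarray:
    """Index-arithmetic nearest-neighbor block replication with cropping."""
    f = 2 ** (level - 1)
    th, tw = target
    out = np.zeros((th, tw))
    for y in range(th):
        for x in range(tw):
            out[y, x] = w[y // f, x // f]
    return out


def loop_detail_fusion(details, weight_maps):
    """Per-pixel weighted sums per level and pointwise max across levels."""
    shape = details[0].shape
    per_level = []
    for maps in weight_maps:
        fused = np.zeros(shape)
        for y in range(shape[0]):
            for x in range(shape[1]):
                fused[y, x] = sum(m[y, x] * d[y, x]
                                  for m, d in zip(maps, details))
        per_level.append(fused)
    combined = np.zeros(shape)
    for y in range(shape[0]):
        for x in range(shape[1]):
            combined[y, x] = max(lvl[y, x] for lvl in per_level)
    return per_level, combined
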