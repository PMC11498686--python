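"""Siamese patch-saliency network, implemented from scratch in NumPy.

Two weight-sharing convolutional branches embed a pair of 16x16 patches;
the concatenated 512-dim embedding feeds a 2-way softmax head whose
probability says which patch is the more salient (sharper, higher-contrast)
one.  Branch layout:

    conv 11x11 pad 5 -> ReLU          (16x16 preserved)
    conv 5x5  pad 2 -> ReLU           (16x16 preserved)
    maxpool 3x3 stride 2 pad 1        (16x16 -> 8x8)
    conv 3x3  pad 1 -> ReLU           (8x8 preserved)
    flatten -> fully connected -> 256-dim branch vector (ReLU)

head: concatenate (512) -> fully connected -> 2 -> softmax.

Channel widths (8, 16, 32) are modest so the desk-scale training task —
discriminating a clean textured patch from its blurred / contrast-crushed
twin — trains in well under a minute on one CPU.  Scoring always evaluates
both input orders and averages, which makes the saliency score exactly
antisymmetric: ``score(a, b) = 1 - score(b, a)``.

Dense inference slides the patch window across a co-registered image pair
and averages each window's softmax probability into every pixel it covers,
yielding a full-resolution weight map in [0, 1] for base-part fusion.

Everything (initialization, pair generation, training order) is driven by
explicit seeds; no deep-learning framework is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ParameterError, TrainingDivergenceError, ValidationError
from .image import ImagePlane

PATCH = 16
BRANCH_DIM = 256
_DT = np.float32


# ---------------------------------------------------------------------------
# minimal functional layers (forward returns a cache for backward)
# ---------------------------------------------------------------------------

def conv_forward(x, w, b, pad):
    """Same-size convolution by shift-and-add over kernel offsets.

    For 16x16 patches this beats im2col: no large gathered copies, just k^2
    small channel contractions.
    """
    n, c, h, wdt = x.shape
    o, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - k + 1, wdt + 2 * pad - k + 1
    out = np.zeros((n, o, ho, wo), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            piece = xp[:, :, di:di + ho, dj:dj + wo]
            # (n,c,ho,wo) x (o,c) -> (n,ho,wo,o)
            out += np.tensordot(piece, w[:, :, di, dj],
                                axes=([1], [1])).transpose(0, 3, 1, 2)
    out += b[None, :, None, None]
    cache = (xp, w, (n, c, h, wdt, k, pad, ho, wo))
    return out, cache


def conv_backward(dout, cache, need_dx=True):
    xp, w, (n, c, h, wdt, k, pad, ho, wo) = cache
    o = w.shape[0]
    dw = np.empty_like(w)
    for di in range(k):
        for dj in range(k):
            piece = xp[:, :, di:di + ho, dj:dj + wo]
            dw[:, :, di, dj] = np.tensordot(dout, piece,
                                            axes=([0, 2, 3], [0, 2, 3]))
    db = dout.sum(axis=(0, 2, 3))
    if not need_dx:
        return None, dw, db
    dxp = np.zeros_like(xp)
    for di in range(k):
        for dj in range(k):
            # (n,o,ho,wo) x (o,c) -> accumulate into the shifted window
            dxp[:, :, di:di + ho, dj:dj + wo] += np.tensordot(
                dout, w[:, :, di, dj], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    dx = dxp[:, :, pad:pad + h, pad:pad + wdt] if pad else dxp
    return dx, dw, db


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def maxpool_forward(x):
    """3x3 window, stride 2, pad 1 (with -inf), e.g. 16x16 -> 8x8."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)),
                constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    win = win[:, :, ::2, ::2]                             # (n,c,ho,wo,3,3)
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, 9)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    cache = (arg, (n, c, h, w, ho, wo))
    return out, cache


def maxpool_backward(dout, cache):
    arg, (n, c, h, w, ho, wo) = cache
    hp, wp = h + 2, w + 2
    ki, kj = arg // 3, arg % 3
    rows = np.arange(ho)[None, None, :, None] * 2 + ki
    colx = np.arange(wo)[None, None, None, :] * 2 + kj
    flatpos = rows * wp + colx                            # (n,c,ho,wo)
    dxp = np.zeros((n, c, hp * wp), dtype=dout.dtype)
    np.add.at(
        dxp,
        (np.arange(n)[:, None, None, None],
         np.arange(c)[None, :, None, None],
         flatpos),
        dout,
    )
    dxp = dxp.reshape(n, c, hp, wp)
    return dxp[:, :, 1:1 + h, 1:1 + w]


def fc_forward(x, w, b):
    return x @ w.T + b, x


def fc_backward(dout, x, w):
    return dout @ w, dout.T @ x, dout.sum(axis=0)


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

_LAYOUT = {  # name -> (out_ch, in_ch, kernel, pad)
    "conv1": (8, 1, 11, 5),
    "conv2": (16, 8, 5, 2),
    "conv3": (32, 16, 3, 1),
}
_FLAT = 32 * 8 * 8


@dataclass
class SiameseNet:
    """Weight-sharing two-branch saliency scorer (see module docstring)."""

    params: Dict[str, np.ndarray]
    seed: int
    history: List[float] = field(default_factory=list)

    # -- forward -----------------------------------------------------------
    def branch(self, x, train=False):
        """Embed (n, 1, 16, 16) patches into (n, 256) vectors."""
        caches = []
        h = x
        for name in ("conv1", "conv2"):
            h, cc = conv_forward(h, self.params[f"{name}_w"],
                                 self.params[f"{name}_b"], _LAYOUT[name][3])
            h, cr = relu_forward(h)
            caches.append((name, cc, cr))
        h, cp = maxpool_forward(h)
        caches.append(("pool", cp, None))
        h, cc = conv_forward(h, self.params["conv3_w"],
                             self.params["conv3_b"], _LAYOUT["conv3"][3])
        h, cr = relu_forward(h)
        caches.append(("conv3", cc, cr))
        flat = h.reshape(h.shape[0], -1)
        caches.append(("flatten", h.shape, None))
        z, cf = fc_forward(flat, self.params["fcb_w"], self.params["fcb_b"])
        feat, cr2 = relu_forward(z)
        caches.append(("fcb", cf, cr2))
        return (feat, caches) if train else feat

    def _branch_backward(self, dfeat, caches, grads):
        name, cf, cr2 = caches[-1]
        dz = relu_backward(dfeat, cr2)
        dflat, dw, db = fc_backward(dz, cf, self.params["fcb_w"])
        grads["fcb_w"] += dw
        grads["fcb_b"] += db
        shape = caches[-2][1]
        dh = dflat.reshape(shape)
        name, cc, cr = caches[-3]
        dh = relu_backward(dh, cr)
        dh, dw, db = conv_backward(dh, cc)
        grads["conv3_w"] += dw
        grads["conv3_b"] += db
        dh = maxpool_backward(dh, caches[-4][1])
        for layer_i, (name, cc, cr) in enumerate(reversed(caches[:2])):
            dh = relu_backward(dh, cr)
            dh, dw, db = conv_backward(dh, cc, need_dx=(layer_i == 0))
            grads[f"{name}_w"] += dw
            grads[f"{name}_b"] += db
        return dh

    def logits(self, a, b, train=False):
        """Head logits for patch batches ``a``, ``b`` (class 0: a salient)."""
        if train:
            fa, ca = self.branch(a, train=True)
            fb, cb = self.branch(b, train=True)
            z = np.concatenate([fa, fb], axis=1)
            out, ch = fc_forward(z, self.params["head_w"],
                                 self.params["head_b"])
            return out, (ca, cb, ch)
        fa = self.branch(a)
        fb = self.branch(b)
        z = np.concatenate([fa, fb], axis=1)
        return z @ self.params["head_w"].T + self.params["head_b"]

    def score(self, a, b):
        """Probability that each ``a`` patch is more salient than its ``b``
        partner; symmetrized over both input orders so that
        ``score(a, b) = 1 - score(b, a)`` exactly."""
        p_ab = softmax(self.logits(a, b))[:, 0]
        p_ba = softmax(self.logits(b, a))[:, 1]
        return 0.5 * (p_ab + p_ba)

    # -- training step -----------------------------------------------------
    def loss_and_grads(self, a, b, labels):
        logits, (ca, cb, ch) = self.logits(a, b, train=True)
        p = softmax(logits)
        n = len(labels)
        eps = np.finfo(_DT).tiny
        loss = float(-np.mean(np.log(p[np.arange(n), labels] + eps)))
        dlogit = p.copy()
        dlogit[np.arange(n), labels] -= 1.0
        dlogit /= n
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dz, dw, db = fc_backward(dlogit.astype(_DT), ch, self.params["head_w"])
        grads["head_w"] += dw
        grads["head_b"] += db
        self._branch_backward(dz[:, :BRANCH_DIM].copy(), ca, grads)
        self._branch_backward(dz[:, BRANCH_DIM:].copy(), cb, grads)
        return loss, grads

    # -- persistence -------------------------------------------------------
    def save(self, path):
        meta = json.dumps({"seed": self.seed, "patch": PATCH,
                           "branch_dim": BRANCH_DIM})
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            params = {k: npz[k] for k in npz.files if k != "__meta__"}
        return cls(params=params, seed=int(meta["seed"]))


def build_snn(seed: int) -> SiameseNet:
    """Initialize the Siamese network from a seeded He-style initializer."""
    rng = np.random.default_rng(int(seed))
    params: Dict[str, np.ndarray] = {}
    for name, (o, c, k, _pad) in _LAYOUT.items():
        scale = np.sqrt(2.0 / (c * k * k))
        params[f"{name}_w"] = (rng.standard_normal((o, c, k, k)) * scale).astype(_DT)
        params[f"{name}_b"] = np.zeros(o, dtype=_DT)
    params["fcb_w"] = (rng.standard_normal((BRANCH_DIM, _FLAT))
                       * np.sqrt(2.0 / _FLAT)).astype(_DT)
    params["fcb_b"] = np.zeros(BRANCH_DIM, dtype=_DT)
    params["head_w"] = (rng.standard_normal((2, 2 * BRANCH_DIM))
                        * np.sqrt(1.0 / (2 * BRANCH_DIM))).astype(_DT)
    params["head_b"] = np.zeros(2, dtype=_DT)
    return SiameseNet(params=params, seed=int(seed))


# ---------------------------------------------------------------------------
# synthetic saliency-discrimination task
# ---------------------------------------------------------------------------

@dataclass
class PatchPairSet:
    """Pairs of 16x16 patches; ``labels[i]`` names the more salient patch
    (0 -> first, 1 -> second).  Balance is enforced exactly."""

    pairs: np.ndarray   # (n, 2, 16, 16)
    labels: np.ndarray  # (n,)
    seed: int


def _textured_patch(rng) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal((PATCH, PATCH)), 0.7)
    noise = (noise - noise.min()) / (np.ptp(noise) + 1e-12)
    xx, yy = np.meshgrid(np.arange(PATCH), np.arange(PATCH), indexing="ij")
    phase = rng.uniform(0, 2 * np.pi)
    freq = rng.uniform(0.15, 0.5)
    angle = rng.uniform(0, np.pi)
    wave = 0.5 + 0.5 * np.sin(freq * (xx * np.cos(angle)
                                      + yy * np.sin(angle)) * 2 * np.pi / 4
                              + phase)
    patch = 0.15 + 0.7 * (0.6 * noise + 0.4 * wave)
    return np.clip(patch, 0.0, 1.0)


def make_patch_pairs(seed: int, n: int, use_blur: bool = True,
                     use_contrast: bool = True) -> PatchPairSet:
    """Generate ``n`` clean/degraded patch pairs with exactly balanced,
    order-randomized labels.

    The degraded twin is Gaussian-blurred (sigma in [1, 3]) and/or has its
    contrast crushed toward the mean (scale in [0.2, 0.6]); the clean patch
    is labelled salient.  With both degradations disabled there is no signal
    to label and a parameter error is raised.
    """
    if n < 2:
        raise ParameterError("need at least two pairs")
    if not (use_blur or use_contrast):
        raise ParameterError(
            "at least one degradation (blur, contrast) must be enabled"
        )
    rng = np.random.default_rng(int(seed))
    labels = np.zeros(n, dtype=np.int64)
    labels[n // 2:] = 1
    rng.shuffle(labels)
    pairs = np.empty((n, 2, PATCH, PATCH), dtype=np.float64)
    for i in range(n):
        clean = _textured_patch(rng)
        bad = clean.copy()
        modes = []
        if use_blur:
            modes.append("blur")
        if use_contrast:
            modes.append("contrast")
        chosen = [m for m in modes if rng.random() < 0.75]
        if not chosen:
            chosen = [modes[rng.integers(len(modes))]]
        if "blur" in chosen:
            bad = gaussian_filter(bad, rng.uniform(1.0, 3.0))
        if "contrast" in chosen:
            s = rng.uniform(0.2, 0.6)
            bad = bad.mean() + s * (bad - bad.mean())
        bad = np.clip(bad, 0.0, 1.0)
        if labels[i] == 0:
            pairs[i, 0], pairs[i, 1] = clean, bad
        else:
            pairs[i, 0], pairs[i, 1] = bad, clean
    return PatchPairSet(pairs=pairs, labels=labels, seed=int(seed))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_snn(model: SiameseNet, data: PatchPairSet, epochs: int = 20,
              learning_rate: float = 1e-3, seed: int = 0,
              batch_size: int = 64) -> Tuple[SiameseNet, float]:
    """Train with Adam on 2-class cross-entropy; 80/20 train/validation
    split drawn from ``seed``.  Returns the model and held-out accuracy."""
    rng = np.random.default_rng(int(seed))
    n = len(data.labels)
    perm = rng.permutation(n)
    n_train = int(round(0.8 * n))
    tr, va = perm[:n_train], perm[n_train:]
    x = data.pairs.astype(_DT)
    y = data.labels

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in model.params.items()}
    t = 0
    b1, b2, eps = 0.9, 0.999, 1e-8
    for epoch in range(int(epochs)):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, batch_size):
            idx = tr[order[start:start + batch_size]]
            a = x[idx, 0][:, None]
            b = x[idx, 1][:, None]
            loss, grads = model.loss_and_grads(a, b, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch, learning_rate)
            losses.append(loss)
            t += 1
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** t)
                vhat = v[k] / (1 - b2 ** t)
                model.params[k] -= (learning_rate * mhat
                                    / (np.sqrt(vhat) + eps)).astype(_DT)
        model.history.append(float(np.mean(losses)))
    acc = evaluate_snn(model, x[va], y[va])
    return model, acc


def evaluate_snn(model: SiameseNet, pairs: np.ndarray,
                 labels: np.ndarray) -> float:
    """Classification accuracy of the symmetric saliency score."""
    s = model.score(pairs[:, 0][:, None].astype(_DT),
                    pairs[:, 1][:, None].astype(_DT))
    pred = (s < 0.5).astype(int)  # score is P(first patch more salient)
    return float(np.mean(pred == labels))


# ---------------------------------------------------------------------------
# dense inference: per-pixel weight map
# ---------------------------------------------------------------------------

def snn_weight_map(img1, img2, model: SiameseNet,
                   stride: int = 2) -> np.ndarray:
    """Slide 16x16 windows over a co-registered pair and average each
    window's source-1 saliency probability into the pixels it covers.

    The result has the input shape and entries in [0, 1]; each pixel's value
    is the coverage-normalized mean of the windows containing it.
    """
    a = img1.pixels if isinstance(img1, ImagePlane) else np.asarray(img1, float)
    b = img2.pixels if isinstance(img2, ImagePlane) else np.asarray(img2, float)
    if a.shape != b.shape:
        raise ValidationError("images must share a shape")
    h, w = a.shape
    if h < PATCH or w < PATCH:
        raise ValidationError(f"images must be at least {PATCH}x{PATCH}")
    if not 1 <= stride <= PATCH:
        raise ParameterError(
            f"stride must lie in [1, {PATCH}] so windows cover every pixel"
        )

    def _positions(extent):
        pos = list(range(0, extent - PATCH + 1, stride))
        if pos[-1] != extent - PATCH:
            pos.append(extent - PATCH)
        return pos

    rows, cols = _positions(h), _positions(w)
    coords = [(r, c) for r in rows for c in cols]
    wins_a = np.stack([a[r:r + PATCH, c:c + PATCH] for r, c in coords])
    wins_b = np.stack([b[r:r + PATCH, c:c + PATCH] for r, c in coords])
    scores = np.empty(len(coords))
    chunk = 1024
    for s0 in range(0, len(coords), chunk):
        scores[s0:s0 + chunk] = model.score(
            wins_a[s0:s0 + chunk, None].astype(_DT),
            wins_b[s0:s0 + chunk, None].astype(_DT),
        )
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for (r, c), s in zip(coords, scores):
        acc[r:r + PATCH, c:c + PATCH] += s
        cnt[r:r + PATCH, c:c + PATCH] += 1.0
    return acc / cnt
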