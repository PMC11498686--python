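"""End-to-end fusion pipeline.

Steps (each optional stage defaults off, matching the assumption of
pre-registered sources):

1. optional preprocessing: rigid registration, anisotropic diffusion,
   histogram equalization;
2. two-scale decomposition of each source into base + detail;
3. base fusion — fixed-scalar weighted sum (default 0.5/0.5) or per-pixel
   Siamese weight map;
4. detail fusion — multi-layer deep-feature activity weights;
5. reconstruction ``F = F_b + F_d``, clipped to [0, 1].

Clipping (not renormalization) is applied because the detail sum can push
bright pixels past 1; clipping preserves absolute intensity semantics.
Under the default optimization decomposition there is no transform to
invert after reconstruction, and under the dual-tree backend the synthesis
already happened inside the decomposition, so the sum is final.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .base_fusion import BaseFusionConfig, fuse_base
from .detail_fusion import DEFAULT_BLOCK_RADIUS, fuse_details
from .exceptions import ParameterError, ValidationError
from .features import extract_features, make_fixture_extractor, make_vgg19_extractor
from .image import ImagePlane, anisodiffuse, hist_equalize, register_rigid
from .siamese import SiameseNet, snn_weight_map
from .twoscale import DEFAULT_LAMBDA, DEFAULT_LEVELS, decompose


@dataclass
class FusionConfig:
    """Everything needed to reproduce one fusion run.

    Round-trips losslessly through ``to_dict``/``from_dict`` (and hence
    through a flat JSON config file).
    """

    decomposition: str = "optimization"   # "optimization" | "dtcwt"
    lam: float = DEFAULT_LAMBDA
    levels: int = DEFAULT_LEVELS
    base_mode: str = "scalar"             # "scalar" | "snn"
    alpha1: float = 0.5
    alpha2: float = 0.5
    extractor: str = "fixture"            # "fixture" | "vgg19"
    extractor_seed: int = 0
    vgg_weights: Optional[str] = None
    snn_weights: Optional[str] = None
    stride: int = 2
    block_radius: int = DEFAULT_BLOCK_RADIUS
    register: bool = False
    register_cost: str = "ssd"
    diffuse: bool = False
    equalize: bool = False
    output_bit_depth: int = 8
    chroma_reinject: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FusionConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "FusionConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FusedImage:
    """A fused result plus the provenance needed to reproduce it."""

    plane: ImagePlane
    provenance: dict = field(default_factory=dict)

    @property
    def pixels(self) -> np.ndarray:
        return self.plane.pixels


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _as_plane(img) -> ImagePlane:
    if isinstance(img, ImagePlane):
        return img
    return ImagePlane(np.asarray(img, float))


def make_extractor(cfg: FusionConfig):
    if cfg.extractor == "fixture":
        return make_fixture_extractor(cfg.extractor_seed)
    if cfg.extractor == "vgg19":
        return make_vgg19_extractor(cfg.vgg_weights)
    raise ParameterError(f"unknown extractor {cfg.extractor!r}")


def fuse(img1, img2, cfg: Optional[FusionConfig] = None,
         snn_model: Optional[SiameseNet] = None) -> FusedImage:
    """Fuse two co-registered single-channel sources (see module docstring).

    ``snn_model`` supplies the Siamese scorer when ``base_mode == "snn"``;
    alternatively ``cfg.snn_weights`` names a saved weights file.
    """
    cfg = cfg or FusionConfig()
    p1, p2 = _as_plane(img1), _as_plane(img2)
    if p1.shape != p2.shape:
        if not cfg.register:
            raise ValidationError(
                f"source shapes differ ({p1.shape} vs {p2.shape}); resize "
                "them or enable registration (register_rigid)"
            )
        raise ValidationError(
            "rigid registration cannot change the image shape; crop or "
            "resample the sources to a common grid first"
        )
    if cfg.register:
        p1, _ = register_rigid(p1, p2, cost=cfg.register_cost)
    if cfg.diffuse:
        p1, p2 = anisodiffuse(p1), anisodiffuse(p2)
    if cfg.equalize:
        p1, p2 = hist_equalize(p1), hist_equalize(p2)

    d1 = decompose(p1.pixels, cfg.decomposition, lam=cfg.lam, levels=cfg.levels)
    d2 = decompose(p2.pixels, cfg.decomposition, lam=cfg.lam, levels=cfg.levels)

    if cfg.base_mode == "snn":
        model = snn_model
        if model is None:
            if cfg.snn_weights is None:
                raise ParameterError(
                    "base_mode='snn' needs a trained model (snn_model=...) "
                    "or cfg.snn_weights pointing at a saved weights file"
                )
            model = SiameseNet.load(cfg.snn_weights)
        # the Siamese scorer sees the full sources; its weight map blends
        # the base parts
        wmap = snn_weight_map(p1, p2, model, stride=cfg.stride)
        base_cfg = BaseFusionConfig(mode="snn", weight_map=wmap)
    else:
        base_cfg = BaseFusionConfig(mode="scalar", alpha1=cfg.alpha1,
                                    alpha2=cfg.alpha2)
    fused_base = fuse_base(d1.base, d2.base, base_cfg)

    extractor = make_extractor(cfg)
    stacks = [extract_features(d.detail, extractor) for d in (d1, d2)]
    fused_detail = fuse_details([d1.detail, d2.detail], stacks,
                                r=cfg.block_radius).combined

    fused = np.clip(fused_base + fused_detail, 0.0, 1.0)
    provenance = {
        "config": cfg.to_dict(),
        "inputs": [p1.meta.get("path", "<array>"),
                   p2.meta.get("path", "<array>")],
        "input_hashes": [_hash(p1.pixels), _hash(p2.pixels)],
        "extractor_id": extractor.extractor_id,
        "output_hash": _hash(fused),
    }
    meta = {"fused": True}
    if cfg.chroma_reinject and "color" in p2.meta:
        meta["color"] = p2.meta["color"]
    plane = ImagePlane(fused, source_bit_depth=p1.source_bit_depth, meta=meta)
    return FusedImage(plane=plane, provenance=provenance)


# ---------------------------------------------------------------------------
# chroma handling for pseudo-colored functional images
# ---------------------------------------------------------------------------

def chroma_reinject(fused: FusedImage, color_source: ImagePlane) -> np.ndarray:
    """Recompose a color image: the fused luminance replaces the Y channel
    of the functional image's YCbCr representation.

    ``color_source`` must carry its original RGB data in ``meta['color']``
    (as :func:`medifuse.image.read_image` stores it).  Returns an (H, W, 3)
    float array in [0, 1].
    """
    if "color" not in color_source.meta:
        raise ParameterError(
            "color_source has no stored chroma (meta['color'] missing); "
            "read the color image with read_image"
        )
    rgb = np.asarray(color_source.meta["color"], float)
    y = fused.pixels
    if rgb.shape[:2] != y.shape:
        raise ValidationError("color source and fused image shapes differ")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cb = -0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 0.5 * r - 0.418688 * g - 0.081312 * b
    out = np.stack([
        y + 1.402 * cr,
        y - 0.344136 * cb - 0.714136 * cr,
        y + 1.772 * cb,
    ], axis=-1)
    return np.clip(out, 0.0, 1.0)
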