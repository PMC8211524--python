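"""Layer fusion and two-scale reconstruction: the public entry point.

``fuse`` runs the full pipeline on a pair of co-registered sources:
two-scale decomposition of each image, one saliency comparison on the
sources, guided-filter refinement of the binary decision under the base
and detail parameter regimes, per-pixel weighted sums of the base and
detail layers, and reconstruction of the fused image as their sum.  All
intermediates are retained on the result object for inspection.

Registration is assumed, not performed: both inputs must depict the same
scene on the same pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FusionConfig
from .decomposition import LayerPair, decompose
from .weights import (
    WeightMap,
    compare_saliency,
    normalize_pair,
    refine_weights,
    saliency,
)
from .filters import as_gray_image

__all__ = ["FusedResult", "fuse_layers", "fuse"]


@dataclass(frozen=True)
class FusedResult:
    """Fused image plus every intermediate of the pipeline.

    ``fused`` is clipped to [0, 1]; before clipping it equals
    ``fused_base + fused_detail`` exactly.  ``weights`` holds the four
    normalized maps keyed ``"base_1"``, ``"base_2"``, ``"detail_1"``,
    ``"detail_2"``; ``layers`` the two base/detail splits.
    """

    fused: np.ndarray
    fused_base: np.ndarray
    fused_detail: np.ndarray
    weights: dict
    layers: tuple
    config: FusionConfig


def fuse_layers(l1, l2, w1: WeightMap, w2: WeightMap) -> np.ndarray:
    """Per-pixel weighted sum of two layers with a normalized weight pair."""
    l1 = as_gray_image(l1, name="layer 1", min_size=1)
    l2 = as_gray_image(l2, name="layer 2", min_size=1)
    for w in (w1, w2):
        if not isinstance(w, WeightMap) or w.stage != "normalized":
            raise ValueError("fuse_layers requires normalized-stage WeightMaps")
    if not (l1.shape == l2.shape == w1.shape == w2.shape):
        raise ValueError("layers and weight maps must share one shape")
    if np.max(np.abs(w1.values + w2.values - 1.0)) > 1e-6:
        raise ValueError("weight pair does not sum to 1 per pixel")
    return w1.values * l1 + w2.values * l2


def fuse(img1, img2, cfg: FusionConfig | None = None) -> FusedResult:
    """Fuse two co-registered single-channel images.

    Returns the fused image together with the fused base/detail layers,
    the four normalized weight maps, and the two decompositions.
    """
    cfg = cfg or FusionConfig()
    img1 = as_gray_image(img1, name="image 1")
    img2 = as_gray_image(img2, name="image 2")
    if img1.shape != img2.shape:
        raise ValueError(f"source images differ in size: {img1.shape} vs {img2.shape}")
    h, w = img1.shape
    need = max(cfg.gaussian_size, 2 * cfg.base_radius + 1, 4 * cfg.subsample_base,
               4 * cfg.subsample_detail)
    if min(h, w) < need:
        raise ValueError(
            f"images of size {h}x{w} are smaller than the largest filter window "
            f"({need} px); reduce base_radius/gaussian_size/subsample or supply "
            f"larger images"
        )

    layers1 = decompose(img1, cfg.base_radius,
                        lbp_neighbors=cfg.lbp_neighbors, lbp_radius=cfg.lbp_radius)
    layers2 = decompose(img2, cfg.base_radius,
                        lbp_neighbors=cfg.lbp_neighbors, lbp_radius=cfg.lbp_radius)

    s1 = saliency(img1, cfg)
    s2 = saliency(img2, cfg)
    p1, p2 = compare_saliency(s1, s2, cfg.tie_rule)

    # each source's weight map is refined with that source as guidance
    w1b = refine_weights(p1, img1, cfg.r1, cfg.eps1, cfg.subsample_base)
    w2b = refine_weights(p2, img2, cfg.r1, cfg.eps1, cfg.subsample_base)
    w1d = refine_weights(p1, img1, cfg.r2, cfg.eps2, cfg.subsample_detail)
    w2d = refine_weights(p2, img2, cfg.r2, cfg.eps2, cfg.subsample_detail)
    w1b, w2b = normalize_pair(w1b, w2b)
    w1d, w2d = normalize_pair(w1d, w2d)

    fused_base = fuse_layers(layers1.base, layers2.base, w1b, w2b)
    fused_detail = fuse_layers(layers1.detail, layers2.detail, w1d, w2d)
    fused = np.clip(fused_base + fused_detail, 0.0, 1.0)

    return FusedResult(
        fused=fused,
        fused_base=fused_base,
        fused_detail=fused_detail,
        weights={"base_1": w1b, "base_2": w2b, "detail_1": w1d, "detail_2": w2d},
        layers=(layers1, layers2),
        config=cfg,
    )
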