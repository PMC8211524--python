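"""Saliency maps and fusion weight construction.

The decision map for fusing two co-registered sources is built in three
stages.  First, each source's saliency map is the local average of its
absolute Laplacian response: Laplacian filtering extracts the high-pass
component and a Gaussian low-pass of its magnitude measures local detail
strength.  Second, the two saliency maps are compared pixel-wise into a
pair of binary weight maps that partition the image (ties go to the first
source so the pair always sums to one).  Third, each binary map is
refined with a fast guided filter, guided by its own source image, so the
weights follow intensity boundaries instead of the jagged binary
decision; the base-layer regime (large radius, strong regularization)
yields spatially smooth weights, the detail-layer regime (small radius,
tiny regularization) keeps them sharp.  A final per-pixel normalization
makes each refined pair sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FusionConfig
from .filters import (
    GuidedFilterParams,
    as_gray_image,
    fast_guided_filter,
    gaussian_lowpass,
    laplacian_filter,
)

__all__ = [
    "WeightMap",
    "saliency",
    "compare_saliency",
    "refine_weights",
    "normalize_pair",
]

STAGES = ("binary", "refined", "normalized")


@dataclass(frozen=True)
class WeightMap:
    """Per-pixel fusion weights in [0, 1] with a provenance stage.

    ``binary`` maps come from the saliency comparison and take values in
    {0, 1}; ``refined`` maps are guided-filter outputs clipped to [0, 1];
    ``normalized`` maps are members of a pair that sums to one per pixel.
    """

    values: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown weight stage {self.stage!r}")
        vals = as_gray_image(self.values, name="weight map", min_size=1)
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("weight values must lie in [0, 1]")
        if self.stage == "binary" and not np.all((vals == 0.0) | (vals == 1.0)):
            raise ValueError("binary-stage weights must be exactly 0 or 1")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self):
        return self.values.shape


def saliency(img, cfg: FusionConfig | None = None) -> np.ndarray:
    """Detail-strength map: Gaussian-smoothed absolute Laplacian response.

    The absolute value is taken between the two convolutions, so the map
    is a non-negative local average of high-pass energy; it vanishes on
    the interior of any affine image.
    """
    cfg = cfg or FusionConfig()
    arr = as_gray_image(img, min_size=cfg.gaussian_size)
    return gaussian_lowpass(
        np.abs(laplacian_filter(arr)), cfg.gaussian_size, cfg.gaussian_sigma
    )


def compare_saliency(
    s1, s2, tie_rule: str = "first-wins"
) -> tuple[WeightMap, WeightMap]:
    """Binary weight maps from a pixel-wise saliency comparison.

    The first map marks pixels where the first source is at least as
    salient; the second map is its complement, so the pair partitions the
    image.  Only the ``"first-wins"`` tie rule is defined: a naive
    symmetric >= on both sides would set both maps to 1 on ties and break
    the partition.
    """
    s1 = as_gray_image(s1, name="saliency map 1", min_size=1)
    s2 = as_gray_image(s2, name="saliency map 2", min_size=1)
    if s1.shape != s2.shape:
        raise ValueError(f"saliency maps differ in size: {s1.shape} vs {s2.shape}")
    if tie_rule != "first-wins":
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    p1 = (s1 >= s2).astype(np.float64)
    return WeightMap(p1, "binary"), WeightMap(1.0 - p1, "binary")


def refine_weights(
    p: WeightMap, guide, r: int, eps: float, s: int = 1
) -> WeightMap:
    """Edge-aware refinement of a binary weight map.

    Runs the fast guided filter on the binary map with the corresponding
    source image as guidance and clips the result to [0, 1].  All-zero and
    all-one maps are fixed points (constant inputs pass through the guided
    filter unchanged).
    """
    if not isinstance(p, WeightMap) or p.stage != "binary":
        raise ValueError("refine_weights expects a binary-stage WeightMap")
    refined = fast_guided_filter(
        p.values, guide, GuidedFilterParams(radius=r, eps=eps, subsample=s)
    )
    return WeightMap(np.clip(refined, 0.0, 1.0), "refined")


def normalize_pair(w1: WeightMap, w2: WeightMap) -> tuple[WeightMap, WeightMap]:
    """Rescale a refined pair so the weights sum to one at every pixel.

    Where both weights are (numerically) zero the pair falls back to an
    even 0.5/0.5 split.
    """
    for w in (w1, w2):
        if not isinstance(w, WeightMap) or w.stage != "refined":
            raise ValueError("normalize_pair expects refined-stage WeightMaps")
    if w1.shape != w2.shape:
        raise ValueError(f"weight maps differ in size: {w1.shape} vs {w2.shape}")
    total = w1.values + w2.values
    ok = total > 1e-9
    n1 = np.where(ok, np.divide(w1.values, total, out=np.zeros_like(total), where=ok), 0.5)
    n2 = np.where(ok, np.divide(w2.values, total, out=np.zeros_like(total), where=ok), 0.5)
    # division rounding can overshoot 1 by one ulp; clamp without
    # disturbing the pairwise sum beyond that ulp
    return (
        WeightMap(np.clip(n1, 0.0, 1.0), "normalized"),
        WeightMap(np.clip(n2, 0.0, 1.0), "normalized"),
    )
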