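"""Pipeline configuration.

All tunables of the fusion pipeline live in one dataclass so a run can be
reproduced from a flat key/value snapshot.  The two guided-filter regimes
follow the usual two-scale fusion convention: a large radius with strong
regularization produces spatially smooth base-layer weights, while a small
radius with nearly vanishing regularization keeps detail-layer weights
sharp and aligned with edges of the guidance image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

__all__ = ["FusionConfig"]

_TIE_RULES = ("first-wins",)


@dataclass
class FusionConfig:
    """Tunable parameters of the fusion pipeline.

    Parameters
    ----------
    r1, eps1 : base-layer weight refinement regime; large window radius
        (pixels) and strong regularization give spatially smooth weights.
    r2, eps2 : detail-layer regime; small radius and near-zero
        regularization keep the refined weights edge-aligned and sharp.
    subsample_base, subsample_detail : subsampling ratio of the fast
        guided filter per regime (1 = exact filter).
    gaussian_size, gaussian_sigma : window size (odd, pixels) and standard
        deviation of the Gaussian low-pass used when building saliency maps.
    base_radius : box-window radius of the two-scale decomposition; the
        base layer is the (2*base_radius+1)^2 window mean.
    lbp_neighbors, lbp_radius : circular local-binary-pattern sampling
        parameters for the low-level-feature descriptor.
    tie_rule : how equal saliency is resolved when binarizing weight maps;
        only ``"first-wins"`` is defined (the first image takes the pixel).
    seed : seed recorded in run manifests; the fusion path itself is
        deterministic.
    """

    r1: int = 45
    eps1: float = 0.25
    r2: int = 7
    eps2: float = 1e-6
    subsample_base: int = 4
    subsample_detail: int = 1
    gaussian_size: int = 11
    gaussian_sigma: float = 5.0
    base_radius: int = 15
    lbp_neighbors: int = 8
    lbp_radius: int = 1
    tie_rule: str = "first-wins"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.r1 < 1 or self.r2 < 1 or self.base_radius < 1:
            raise ValueError("filter radii must be >= 1 pixel")
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("regularization eps must be > 0 in the pipeline")
        if self.subsample_base < 1 or self.subsample_detail < 1:
            raise ValueError("subsample ratios must be integers >= 1")
        if self.gaussian_size < 3 or self.gaussian_size % 2 == 0:
            raise ValueError("gaussian_size must be odd and >= 3")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.lbp_neighbors != 8:
            raise ValueError("only 8-neighbor LBP codes are supported")
        if self.lbp_radius < 1:
            raise ValueError("lbp_radius must be >= 1")
        if self.tie_rule not in _TIE_RULES:
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}; choose from {_TIE_RULES}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "FusionConfig":
        """Build a config from a flat mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def replace(self, **updates: Any) -> "FusionConfig":
        merged = self.to_dict()
        merged.update(updates)
        return FusionConfig.from_mapping(merged)
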