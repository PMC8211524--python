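"""Synthetic ground-truth phantoms and complementary-focus input pairs.

Real multifocus/multimodal benchmark pairs come from clinical databases
that cannot ship with a library.  This module generates a stand-in corpus
at test time: anatomy-like phantoms (overlapping soft-edged ellipses over
a flat background, plus band-limited texture) and complementary-focus
pairs derived from a phantom, where each input is sharp inside a mask and
Gaussian-blurred outside, with the two masks exact complements.  Every
pixel is therefore sharp in exactly one input — the precondition that
focus-driven fusion relies on — and the phantom itself is the ground
truth against which fusion quality can be scored.

All generation is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import as_gray_image, gaussian_lowpass
from .weights import WeightMap

__all__ = ["PhantomSpec", "FocusPairSpec", "make_phantom", "make_focus_pair"]

MASK_KINDS = ("half-split", "radial", "random-blobs")

_BACKGROUND = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an anatomy-like phantom.

    size is the square side in pixels; n_ellipses the number of soft
    ellipses drawn over the background; texture_amp the peak amplitude of
    the band-limited texture field (intensity units).
    """

    size: int = 256
    n_ellipses: int = 6
    texture_amp: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("phantom size must be >= 64 pixels")
        if self.n_ellipses < 0 or self.texture_amp < 0:
            raise ValueError("n_ellipses and texture_amp must be non-negative")


@dataclass(frozen=True)
class FocusPairSpec:
    """Parameters of a complementary-focus pair.

    blur_sigma is the Gaussian blur applied to the out-of-focus region;
    mask_kind selects the sharp-region geometry: "half-split" (left/right
    halves), "radial" (a disk), or "random-blobs" (thresholded smooth
    noise with thin structures).
    """

    blur_sigma: float = 2.0
    mask_kind: str = "half-split"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")
        if self.mask_kind not in MASK_KINDS:
            raise ValueError(f"mask_kind must be one of {MASK_KINDS}")


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_phantom(spec: PhantomSpec | None = None, **kwargs) -> np.ndarray:
    """Deterministic anatomy-like test image in [0, 1].

    Soft-edged ellipses of varied intensity, orientation and eccentricity
    are layered over a flat background; a low-pass-filtered noise field of
    amplitude ``texture_amp`` adds fine texture everywhere so that detail
    layers and saliency maps are non-trivial.
    """
    spec = spec or PhantomSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    img = np.full((n, n), _BACKGROUND, dtype=np.float64)
    yy, xx = np.mgrid[0:n, 0:n] / (n - 1.0)

    for _ in range(spec.n_ellipses):
        cy, cx = rng.uniform(0.2, 0.8, size=2)
        ay, ax = rng.uniform(0.08, 0.32, size=2)
        theta = rng.uniform(0.0, np.pi)
        amp = rng.uniform(-0.35, 0.5)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d = np.sqrt((u / ax) ** 2 + (v / ay) ** 2)  # 1 on the boundary
        edge = 0.15  # soft-edge width as a fraction of the ellipse radius
        img += amp * _smoothstep((1.0 - d) / edge)

    if spec.texture_amp > 0:
        noise = rng.standard_normal((n, n))
        texture = gaussian_lowpass(noise, 9, 1.5)
        peak = np.max(np.abs(texture))
        if peak > 0:
            img += spec.texture_amp * texture / peak

    return np.clip(img, 0.0, 1.0)


def _make_mask(shape: tuple[int, int], kind: str, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "half-split":
        return (xx < w // 2).astype(np.float64)
    if kind == "radial":
        cy = rng.uniform(0.4, 0.6) * (h - 1)
        cx = rng.uniform(0.4, 0.6) * (w - 1)
        radius = rng.uniform(0.25, 0.4) * min(h, w)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        return (dist <= radius).astype(np.float64)
    # random-blobs: thresholded smooth noise, median split so both inputs
    # carry a substantial sharp region
    field = gaussian_lowpass(rng.standard_normal((h, w)), 33, 8.0)
    return (field >= np.median(field)).astype(np.float64)


def make_focus_pair(
    gt, spec: FocusPairSpec | None = None, **kwargs
) -> tuple[np.ndarray, np.ndarray, WeightMap]:
    """Complementary-focus inputs (A, B) plus the ground-truth focus mask.

    A equals the ground truth inside the mask and its Gaussian blur
    outside; B is the exact complement.  The returned binary mask marks
    the region where A is the sharp source.
    """
    gt = as_gray_image(gt, name="ground truth")
    spec = spec or FocusPairSpec(**kwargs)
    rng = np.random.default_rng(spec.seed)
    ksize = 2 * int(np.ceil(3.0 * spec.blur_sigma)) + 1
    ksize = max(ksize, 3)
    blurred = gaussian_lowpass(gt, ksize, spec.blur_sigma)
    mask = _make_mask(gt.shape, spec.mask_kind, rng)
    a = np.where(mask > 0, gt, blurred)
    b = np.where(mask > 0, blurred, gt)
    return a, b, WeightMap(mask, "binary")
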