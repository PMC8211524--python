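"""Two-scale decomposition and the local-binary-pattern descriptor.

Each source image is split into a low-frequency base layer (a large-window
mean) and a signed detail layer (the residual), so that base + detail
reconstructs the source exactly.  Alongside the structural split, a
circular local-binary-pattern (LBP) code map is computed as the image's
low-level texture descriptor: each pixel's code packs the comparisons of
circularly sampled neighbors against the center intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .filters import as_gray_image, box_filter

__all__ = ["LbpMap", "LayerPair", "lbp_code", "decompose"]


@dataclass(frozen=True)
class LbpMap:
    """Per-pixel LBP codes in [0, 2**neighbors - 1].

    Bit 0 corresponds to the sample due east of the pixel; subsequent bits
    proceed counter-clockwise around the circle of the given radius.  A
    sample greater than or equal to the center sets its bit.
    """

    codes: np.ndarray
    neighbors: int
    radius: int


@dataclass(frozen=True)
class LayerPair:
    """Base/detail split of one source image.

    ``base + detail`` equals the source to machine precision, and the base
    layer (a window mean) stays within the source's intensity range.  The
    LBP descriptor of the source rides along for inspection; it does not
    alter the split.
    """

    base: np.ndarray
    detail: np.ndarray
    lbp: Optional[LbpMap] = None

    @property
    def source(self) -> np.ndarray:
        return self.base + self.detail


def lbp_code(img, neighbors: int = 8, radius: int = 1) -> LbpMap:
    """Circular LBP codes with bilinear sampling and mirror borders.

    Off-grid circle samples are bilinearly interpolated; samples falling
    outside the frame use mirror reflection, so every pixel (borders
    included) receives a code.  The >= comparison allows a 1e-9 absolute
    slack so that exact ties (e.g. a constant image) are not broken by
    interpolation rounding.
    """
    arr = as_gray_image(img)
    if neighbors != 8:
        raise ValueError("only 8-neighbor LBP codes are supported")
    if radius < 1:
        raise ValueError("LBP radius must be >= 1")
    h, w = arr.shape
    if radius >= min(h, w) / 2:
        raise ValueError(
            f"LBP radius {radius} too large for a {h}x{w} image (must be < min(H, W)/2)"
        )
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    codes = np.zeros((h, w), dtype=np.int32)
    for bit in range(neighbors):
        theta = 2.0 * np.pi * bit / neighbors
        # image rows grow downward, so counter-clockwise means -sin on rows
        sr = rows - radius * np.sin(theta)
        sc = cols + radius * np.cos(theta)
        sample = ndimage.map_coordinates(arr, [sr, sc], order=1, mode="mirror")
        codes |= (sample >= arr - 1e-9).astype(np.int32) << bit
    return LbpMap(codes=codes, neighbors=neighbors, radius=radius)


def decompose(
    img,
    base_radius: int = 15,
    *,
    lbp_neighbors: int = 8,
    lbp_radius: int = 1,
    with_lbp: bool = True,
) -> LayerPair:
    """Split ``img`` into base (window mean) and detail (residual) layers.

    The base layer is the (2*base_radius+1)^2 box mean with mirror
    borders; the detail layer is the signed residual, so reconstruction is
    exact by construction.
    """
    arr = as_gray_image(img)
    base = box_filter(arr, base_radius)
    detail = arr - base
    lbp = lbp_code(arr, lbp_neighbors, lbp_radius) if with_lbp else None
    return LayerPair(base=base, detail=detail, lbp=lbp)
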