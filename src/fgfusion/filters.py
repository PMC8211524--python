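"""Spatial filtering primitives.

All window operations use mirror border handling (edge reflection without
repeating the border pixel) so that window means near the frame carry no
dark-frame bias.  Images are plain 2-D float64 :class:`numpy.ndarray`
objects ("gray images"): intensities are nominally in [0, 1], but signed
values are permitted for detail layers and high-pass responses.

The guided filter expresses its output as a local linear function of a
guidance image: within each (2r+1)x(2r+1) window the coefficients (a, b)
of ``output = a * guide + b`` are obtained by ridge regression of the
filter input against the guide, and the per-window coefficients are then
averaged over all windows covering a pixel.  The fast variant computes the
coefficient maps on a subsampled grid and bilinearly upsamples them, which
makes the cost independent of the filter radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "GuidedFilterParams",
    "as_gray_image",
    "box_filter",
    "laplacian_filter",
    "gaussian_lowpass",
    "gaussian_kernel",
    "guided_filter",
    "fast_guided_filter",
]

LAPLACIAN_KERNEL = np.array(
    [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
)


def as_gray_image(img, *, name: str = "image", min_size: int = 3) -> np.ndarray:
    """Validate and coerce ``img`` to a 2-D float64 array.

    Rejects non-2-D inputs, images smaller than ``min_size`` in either
    dimension, and any non-finite value.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(
            f"{name} must be at least {min_size}x{min_size}, got {arr.shape[0]}x{arr.shape[1]}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class GuidedFilterParams:
    """Radius (pixels), regularization and subsample ratio of a guided filter.

    ``subsample == 1`` selects the exact filter; larger ratios run the
    coefficient regression on a block-mean downsampled grid.
    """

    radius: int
    eps: float
    subsample: int = 1

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1 pixel")
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.subsample < 1:
            raise ValueError("subsample must be an integer >= 1")


def box_filter(img, r: int) -> np.ndarray:
    """Mean of ``img`` over the (2r+1)x(2r+1) window centered at each pixel."""
    arr = as_gray_image(img)
    if int(r) != r or r < 1:
        raise ValueError("box radius must be an integer >= 1")
    return ndimage.uniform_filter(arr, size=2 * int(r) + 1, mode="mirror")


def laplacian_filter(img) -> np.ndarray:
    """4-neighbor discrete Laplacian; signed high-pass response."""
    arr = as_gray_image(img)
    return ndimage.convolve(arr, LAPLACIAN_KERNEL, mode="mirror")


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """size x size Gaussian kernel renormalized to sum exactly 1."""
    if size < 3 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_lowpass(img, size: int, sigma: float) -> np.ndarray:
    """Convolution with a normalized size x size Gaussian kernel.

    The kernel is separable, so the convolution runs as two 1-D passes;
    with mirror borders this is identical (up to rounding) to the dense
    2-D convolution.
    """
    arr = as_gray_image(img)
    if size < 3 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    half = size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(x**2) / (2.0 * sigma**2))
    g1 = g1 / g1.sum()
    out = ndimage.correlate1d(arr, g1, axis=0, mode="mirror")
    return ndimage.correlate1d(out, g1, axis=1, mode="mirror")


def _guided_coefficients(p, guide, r, eps):
    """Per-pixel averaged regression coefficients (a_bar, b_bar).

    a_k = cov(guide, p) / (var(guide) + eps) per window; b_k makes the
    window means agree.  With eps = 0 and a zero-variance window the
    minimum-norm solution a_k = 0, b_k = mean(p) is used.
    """
    mean_g = box_filter(guide, r)
    mean_p = box_filter(p, r)
    corr_gp = box_filter(guide * p, r)
    corr_gg = box_filter(guide * guide, r)
    cov_gp = corr_gp - mean_g * mean_p
    var_g = np.maximum(corr_gg - mean_g * mean_g, 0.0)
    denom = var_g + eps
    a = np.divide(cov_gp, denom, out=np.zeros_like(cov_gp), where=denom > 0)
    b = mean_p - a * mean_g
    return box_filter(a, r), box_filter(b, r)


def guided_filter(p, guide, r: int, eps: float) -> np.ndarray:
    """Exact guided filter of input ``p`` with guidance image ``guide``."""
    p = as_gray_image(p, name="filter input")
    guide = as_gray_image(guide, name="guidance image")
    if p.shape != guide.shape:
        raise ValueError(
            f"filter input {p.shape} and guidance image {guide.shape} differ in size"
        )
    if int(r) != r or r < 1:
        raise ValueError("radius must be an integer >= 1")
    if eps < 0:
        raise ValueError("eps must be >= 0")
    a_bar, b_bar = _guided_coefficients(p, guide, int(r), float(eps))
    return a_bar * guide + b_bar


def _area_downsample(img: np.ndarray, s: int) -> np.ndarray:
    """Block-mean downsample by integer factor ``s`` (partial edge blocks
    average over the pixels they actually contain)."""
    h, w = img.shape
    ri = np.arange(0, h, s)
    ci = np.arange(0, w, s)
    sums = np.add.reduceat(np.add.reduceat(img, ri, axis=0), ci, axis=1)
    rn = np.diff(np.append(ri, h))
    cn = np.diff(np.append(ci, w))
    return sums / np.outer(rn, cn)


def fast_guided_filter(p, guide, params: GuidedFilterParams) -> np.ndarray:
    """Guided filter with subsampled coefficient computation.

    The filter input and guide are block-mean downsampled by
    ``params.subsample``, the regression runs at low resolution with
    radius ``max(1, round(r/s))``, and the coefficient maps are bilinearly
    upsampled before being applied to the full-resolution guide.  With
    ``subsample == 1`` this is exactly :func:`guided_filter`.
    """
    p = as_gray_image(p, name="filter input")
    guide = as_gray_image(guide, name="guidance image")
    if p.shape != guide.shape:
        raise ValueError(
            f"filter input {p.shape} and guidance image {guide.shape} differ in size"
        )
    s = params.subsample
    if s == 1:
        return guided_filter(p, guide, params.radius, params.eps)
    h, w = p.shape
    if s > min(h, w) / 4:
        raise ValueError(
            f"subsample ratio {s} leaves a degenerate low-resolution grid for a "
            f"{h}x{w} image (requires s <= min(H, W)/4)"
        )
    p_lo = _area_downsample(p, s)
    g_lo = _area_downsample(guide, s)
    r_lo = max(1, round(params.radius / s))
    a_lo, b_lo = _guided_coefficients(p_lo, g_lo, r_lo, params.eps)
    a = resize(a_lo, (h, w), order=1, mode="edge", anti_aliasing=False)
    b = resize(b_lo, (h, w), order=1, mode="edge", anti_aliasing=False)
    return a * guide + b
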