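"""Fusion quality metrics for (source A, source B, fused F) triples.

Four complementary measures of how much information a fused image retains
from its two sources:

* ``mse`` — mean squared error between the fused image and each source on
  the 0-255 intensity scale, averaged over the two sources; lower is
  better.
* ``mutual_information`` — I(A;F) + I(B;F) in bits from 256-bin joint
  histograms of the 8-bit quantized images; higher means more source
  intensity information survives in F.
* ``qabf`` — edge-information transfer: Sobel gradient strength and
  orientation preservation, each mapped through a sigmoid with the
  canonical constants from the fusion-metric literature, combined per
  pixel and averaged with the source gradient strengths as weights.
* ``qy`` — structural preservation: per 7x7 window, a variance-weighted
  blend of SSIM(A,F) and SSIM(B,F) where the sources agree
  (SSIM(A,B) >= 0.75), otherwise the better of the two; averaged over all
  fully interior windows.

All metrics are symmetric in (A, B).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .filters import as_gray_image

__all__ = ["MetricsReport", "mse", "mutual_information", "qabf", "qy", "evaluate"]

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T

# edge-strength / orientation sigmoid constants (canonical published values)
GAMMA_G, KAPPA_G, SIGMA_G = 0.9994, -15.0, 0.5
GAMMA_A, KAPPA_A, SIGMA_A = 0.9879, -22.0, 0.8

# SSIM stabilizers for intensities on the [0, 1] scale
SSIM_C1 = 0.01**2
SSIM_C2 = 0.03**2


@dataclass(frozen=True)
class MetricsReport:
    """All four metrics for one (A, B, F) triple."""

    mse: float
    mi: float
    qabf: float
    qy: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _check_triple(a, b, f, min_size=3):
    a = as_gray_image(a, name="source A", min_size=min_size)
    b = as_gray_image(b, name="source B", min_size=min_size)
    f = as_gray_image(f, name="fused image", min_size=min_size)
    if not (a.shape == b.shape == f.shape):
        raise ValueError(
            f"images differ in size: {a.shape}, {b.shape}, {f.shape}"
        )
    return a, b, f


def mse(a, b, f) -> float:
    """Mean squared error of F against A and B, averaged, on the 0-255 scale."""
    a, b, f = _check_triple(a, b, f)
    ea = np.mean((255.0 * a - 255.0 * f) ** 2)
    eb = np.mean((255.0 * b - 255.0 * f) ** 2)
    return float(0.5 * (ea + eb))


def _quantize(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(255.0 * x), 0, 255).astype(np.intp)


def _mi_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information in bits between two 8-bit quantized images."""
    joint = np.zeros((256, 256), dtype=np.float64)
    np.add.at(joint, (_quantize(x).ravel(), _quantize(y).ravel()), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information(a, b, f) -> float:
    """I(A;F) + I(B;F) in bits, from 256x256 joint histograms."""
    a, b, f = _check_triple(a, b, f)
    return _mi_pair(a, f) + _mi_pair(b, f)


def _sobel(img: np.ndarray):
    gx = ndimage.convolve(img, SOBEL_X, mode="mirror")
    gy = ndimage.convolve(img, SOBEL_Y, mode="mirror")
    # snap summation-order residue to zero so orientations at exactly
    # vertical/horizontal edges (mirror borders included) are stable
    gx[np.abs(gx) < 1e-12] = 0.0
    gy[np.abs(gy) < 1e-12] = 0.0
    g = np.hypot(gx, gy)
    alpha = np.where(
        gx != 0.0,
        np.arctan(np.divide(gy, gx, out=np.zeros_like(gy), where=gx != 0.0)),
        np.pi / 2.0 * np.sign(gy),
    )
    return g, alpha


def _edge_preservation(gs: np.ndarray, alphas: np.ndarray, gf: np.ndarray,
                       alphaf: np.ndarray) -> np.ndarray:
    """Per-pixel edge preservation of one source in the fused image."""
    hi = np.maximum(gs, gf)
    lo = np.minimum(gs, gf)
    ratio = np.divide(lo, hi, out=np.ones_like(hi), where=hi > 0)
    orient = 1.0 - np.abs(alphas - alphaf) / (np.pi / 2.0)
    qg = GAMMA_G / (1.0 + np.exp(KAPPA_G * (ratio - SIGMA_G)))
    qa = GAMMA_A / (1.0 + np.exp(KAPPA_A * (orient - SIGMA_A)))
    return qg * qa


def qabf(a, b, f) -> float:
    """Edge-information transfer from both sources into the fused image.

    The per-pixel preservation factors are weighted by the corresponding
    source gradient strengths; a triple with no gradient anywhere scores
    0 by the zero-total-weight guard.
    """
    a, b, f = _check_triple(a, b, f)
    ga, aa = _sobel(a)
    gb, ab = _sobel(b)
    gf, af = _sobel(f)
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab, gf, af)
    total = np.sum(ga + gb)
    if total <= 0:
        return 0.0
    return float(np.sum(q_af * ga + q_bf * gb) / total)


def _window_stats(x: np.ndarray, y: np.ndarray, size: int):
    r = size // 2
    sl = (slice(r, -r), slice(r, -r))
    mx = ndimage.uniform_filter(x, size=size, mode="mirror")[sl]
    my = ndimage.uniform_filter(y, size=size, mode="mirror")[sl]
    mxx = ndimage.uniform_filter(x * x, size=size, mode="mirror")[sl]
    myy = ndimage.uniform_filter(y * y, size=size, mode="mirror")[sl]
    mxy = ndimage.uniform_filter(x * y, size=size, mode="mirror")[sl]
    vx = np.maximum(mxx - mx * mx, 0.0)
    vy = np.maximum(myy - my * my, 0.0)
    cxy = mxy - mx * my
    return mx, my, vx, vy, cxy


def _ssim_map(x: np.ndarray, y: np.ndarray, size: int) -> np.ndarray:
    mx, my, vx, vy, cxy = _window_stats(x, y, size)
    num = (2.0 * mx * my + SSIM_C1) * (2.0 * cxy + SSIM_C2)
    den = (mx * mx + my * my + SSIM_C1) * (vx + vy + SSIM_C2)
    return num / den


def qy(a, b, f, *, window: int = 7, threshold: float = 0.75) -> float:
    """Structural (SSIM-based) preservation of the sources in the fused image.

    Per interior window: where the sources are structurally consistent
    (SSIM(A,B) >= threshold) the source SSIMs against F are blended with
    the local variance ratio lambda = var_A / (var_A + var_B) (0.5 when
    both variances vanish); elsewhere the better of the two is taken.
    """
    a, b, f = _check_triple(a, b, f, min_size=window)
    s_ab = _ssim_map(a, b, window)
    s_af = _ssim_map(a, f, window)
    s_bf = _ssim_map(b, f, window)
    r = window // 2
    sl = (slice(r, -r), slice(r, -r))
    va = np.maximum(
        ndimage.uniform_filter(a * a, size=window, mode="mirror")[sl]
        - ndimage.uniform_filter(a, size=window, mode="mirror")[sl] ** 2,
        0.0,
    )
    vb = np.maximum(
        ndimage.uniform_filter(b * b, size=window, mode="mirror")[sl]
        - ndimage.uniform_filter(b, size=window, mode="mirror")[sl] ** 2,
        0.0,
    )
    total = va + vb
    lam = np.where(total > 0, np.divide(va, total, out=np.zeros_like(total), where=total > 0), 0.5)
    blended = lam * s_af + (1.0 - lam) * s_bf
    best = np.maximum(s_af, s_bf)
    q = np.where(s_ab >= threshold, blended, best)
    return float(np.mean(q))


def evaluate(a, b, f) -> MetricsReport:
    """All four metrics for one triple."""
    return MetricsReport(
        mse=mse(a, b, f),
        mi=mutual_information(a, b, f),
        qabf=qabf(a, b, f),
        qy=qy(a, b, f),
    )
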