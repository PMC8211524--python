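"""Brute-force reference implementations used to validate the library.

Every oracle here is a literal, loop-based transcription of the
definition it checks: explicit window means, dense convolution sums,
per-window regression, per-pixel code comparison and per-window SSIM.
None of them share code with the package beyond numpy itself.
"""

from __future__ import annotations

import math

import numpy as np


def reflect_pad(img: np.ndarray, pad: int) -> np.ndarray:
    """Mirror padding without repeating the border pixel."""
    return np.pad(img, pad, mode="reflect")


def box_oracle(img: np.ndarray, r: int) -> np.ndarray:
    h, w = img.shape
    p = reflect_pad(img, r)
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = p[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
    return out


def conv2_oracle(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense 2-D convolution with mirror borders (kernel flipped)."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    p = np.pad(img, ((rh, rh), (rw, rw)), mode="reflect")
    flipped = kernel[::-1, ::-1]
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(p[i : i + kh, j : j + kw] * flipped)
    return out


def gaussian_kernel_oracle(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    k = np.empty((size, size))
    for i in range(size):
        for j in range(size):
            k[i, j] = math.exp(-((i - half) ** 2 + (j - half) ** 2) / (2 * sigma**2))
    return k / k.sum()


def guided_oracle(p: np.ndarray, guide: np.ndarray, r: int, eps: float) -> np.ndarray:
    """Literal per-window linear-regression guided filter."""
    h, w = p.shape
    pp = reflect_pad(p, r)
    gg = reflect_pad(guide, r)
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            iw = gg[i : i + 2 * r + 1, j : j + 2 * r + 1]
            pw = pp[i : i + 2 * r + 1, j : j + 2 * r + 1]
            u = iw.mean()
            var = max((iw * iw).mean() - u * u, 0.0)
            pbar = pw.mean()
            cov = (iw * pw).mean() - u * pbar
            denom = var + eps
            a[i, j] = cov / denom if denom > 0 else 0.0
            b[i, j] = pbar - a[i, j] * u
    a_bar = box_oracle(a, r)
    b_bar = box_oracle(b, r)
    return a_bar * guide + b_bar


def _bilinear_mirror(img: np.ndarray, y: float, x: float, pad: int) -> float:
    p = reflect_pad(img, pad)
    y += pad
    x += pad
    y0, x0 = int(math.floor(y)), int(math.floor(x))
    fy, fx = y - y0, x - x0
    return (
        p[y0, x0] * (1 - fy) * (1 - fx)
        + p[y0, x0 + 1] * (1 - fy) * fx
        + p[y0 + 1, x0] * fy * (1 - fx)
        + p[y0 + 1, x0 + 1] * fy * fx
    )


def lbp_oracle(img: np.ndarray, neighbors: int = 8, radius: int = 1) -> np.ndarray:
    """Direct per-pixel circular-comparison codes (bit 0 east, CCW)."""
    h, w = img.shape
    pad = int(math.ceil(radius)) + 1
    codes = np.zeros((h, w), dtype=np.int32)
    for i in range(h):
        for j in range(w):
            code = 0
            for bit in range(neighbors):
                theta = 2.0 * math.pi * bit / neighbors
                sy = i - radius * math.sin(theta)
                sx = j + radius * math.cos(theta)
                sample = _bilinear_mirror(img, sy, sx, pad)
                if sample >= img[i, j] - 1e-9:
                    code |= 1 << bit
            codes[i, j] = code
    return codes


def mse_oracle(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    h, w = a.shape
    ea = eb = 0.0
    for i in range(h):
        for j in range(w):
            ea += (255 * a[i, j] - 255 * f[i, j]) ** 2
            eb += (255 * b[i, j] - 255 * f[i, j]) ** 2
    n = h * w
    return 0.5 * (ea / n + eb / n)


def _mi_pair_oracle(x: np.ndarray, y: np.ndarray) -> float:
    xq = np.clip(np.round(255 * x), 0, 255).astype(int)
    yq = np.clip(np.round(255 * y), 0, 255).astype(int)
    n = xq.size
    joint: dict[tuple[int, int], int] = {}
    px: dict[int, int] = {}
    py: dict[int, int] = {}
    for u, v in zip(xq.ravel(), yq.ravel()):
        joint[(u, v)] = joint.get((u, v), 0) + 1
        px[u] = px.get(u, 0) + 1
        py[v] = py.get(v, 0) + 1
    mi = 0.0
    for (u, v), c in joint.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((px[u] / n) * (py[v] / n)))
    return mi


def mi_oracle(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    return _mi_pair_oracle(a, f) + _mi_pair_oracle(b, f)


_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def _sobel_oracle(img: np.ndarray):
    h, w = img.shape
    p = reflect_pad(img, 1)
    g = np.zeros((h, w))
    alpha = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win = p[i : i + 3, j : j + 3]
            # correlation with the symmetric-flip kernels
            gx = np.sum(win * _SOBEL_X[::-1, ::-1])
            gy = np.sum(win * _SOBEL_X.T[::-1, ::-1])
            if abs(gx) < 1e-12:
                gx = 0.0
            if abs(gy) < 1e-12:
                gy = 0.0
            g[i, j] = math.hypot(gx, gy)
            if gx != 0.0:
                alpha[i, j] = math.atan(gy / gx)
            elif gy > 0:
                alpha[i, j] = math.pi / 2
            elif gy < 0:
                alpha[i, j] = -math.pi / 2
    return g, alpha


def qabf_oracle(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    gg, kg, sg = 0.9994, -15.0, 0.5
    ga_, ka, sa = 0.9879, -22.0, 0.8
    sa_g, sa_al = _sobel_oracle(a)
    sb_g, sb_al = _sobel_oracle(b)
    sf_g, sf_al = _sobel_oracle(f)

    def preserve(gs, als, gf, alf):
        hi, lo = max(gs, gf), min(gs, gf)
        ratio = lo / hi if hi > 0 else 1.0
        orient = 1.0 - abs(als - alf) / (math.pi / 2)
        qg = gg / (1.0 + math.exp(kg * (ratio - sg)))
        qa = ga_ / (1.0 + math.exp(ka * (orient - sa)))
        return qg * qa

    h, w = a.shape
    num = den = 0.0
    for i in range(h):
        for j in range(w):
            qaf = preserve(sa_g[i, j], sa_al[i, j], sf_g[i, j], sf_al[i, j])
            qbf = preserve(sb_g[i, j], sb_al[i, j], sf_g[i, j], sf_al[i, j])
            num += qaf * sa_g[i, j] + qbf * sb_g[i, j]
            den += sa_g[i, j] + sb_g[i, j]
    return num / den if den > 0 else 0.0


def qy_oracle(a: np.ndarray, b: np.ndarray, f: np.ndarray,
              window: int = 7, threshold: float = 0.75) -> float:
    c1, c2 = 0.01**2, 0.03**2
    r = window // 2
    h, w = a.shape

    def stats(x, y):
        mx, my = x.mean(), y.mean()
        vx = max((x * x).mean() - mx * mx, 0.0)
        vy = max((y * y).mean() - my * my, 0.0)
        cxy = (x * y).mean() - mx * my
        return mx, my, vx, vy, cxy

    def ssim(x, y):
        mx, my, vx, vy, cxy = stats(x, y)
        return ((2 * mx * my + c1) * (2 * cxy + c2)) / (
            (mx * mx + my * my + c1) * (vx + vy + c2)
        )

    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            wa = a[i - r : i + r + 1, j - r : j + r + 1]
            wb = b[i - r : i + r + 1, j - r : j + r + 1]
            wf = f[i - r : i + r + 1, j - r : j + r + 1]
            s_ab = ssim(wa, wb)
            s_af = ssim(wa, wf)
            s_bf = ssim(wb, wf)
            va = max((wa * wa).mean() - wa.mean() ** 2, 0.0)
            vb = max((wb * wb).mean() - wb.mean() ** 2, 0.0)
            if va + vb > 0:
                lam = va / (va + vb)
            else:
                lam = 0.5
            if s_ab >= threshold:
                vals.append(lam * s_af + (1 - lam) * s_bf)
            else:
                vals.append(max(s_af, s_bf))
    return float(np.mean(vals))
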