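"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately written with plain loops, explicit padding,
and direct DFT construction, sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def conv_oracle(img: np.ndarray, kern: np.ndarray, border: str = "reflect") -> np.ndarray:
    """Direct nested-loop 2-D correlation of a 2-D array with a square kernel."""
    r = kern.shape[0] // 2
    if border == "reflect":
        padded = np.pad(img, r, mode="symmetric")
    else:
        padded = np.pad(img, r, mode="constant")
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            s = 0.0
            for i in range(-r, r + 1):
                for j in range(-r, r + 1):
                    s += padded[y + r + i, x + r + j] * kern[i + r, j + r]
            out[y, x] = s
    return out


def tconv_oracle(x: np.ndarray, kern: np.ndarray, stride: int) -> np.ndarray:
    """Direct scatter-and-sum transposed convolution of a 2-D array,
    symmetrically cropped/padded to (stride*H, stride*W)."""
    h, w = x.shape
    k = kern.shape[0]
    full = np.zeros((stride * (h - 1) + k, stride * (w - 1) + k))
    for y in range(h):
        for xx in range(w):
            for a in range(k):
                for b in range(k):
                    full[stride * y + a, stride * xx + b] += x[y, xx] * kern[a, b]
    th, tw = stride * h, stride * w
    out = np.zeros((th, tw))
    fh, fw = full.shape
    oy = (fh - th) // 2 if fh >= th else -((th - fh) // 2)
    ox = (fw - tw) // 2 if fw >= tw else -((tw - fw) // 2)
    for y in range(th):
        for xx in range(tw):
            sy, sx = y + oy, xx + ox
            if 0 <= sy < fh and 0 <= sx < fw:
                out[y, xx] = full[sy, sx]
    return out


_SOB_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)


def ebs_oracle(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Per-pixel loop evaluation of the edge-transfer index Q^AB/F on 2-D
    luminance arrays, with the standard sigmoid constants."""

    def grad(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = conv_oracle(img, _SOB_X)
        gy = conv_oracle(img, _SOB_X.T)
        mag = np.sqrt(g**2 + gy**2)
        ang = np.mod(np.arctan2(gy, g) + np.pi / 2, np.pi) - np.pi / 2
        return mag, ang

    ga, aa = grad(a)
    gb, ab = grad(b)
    gf, af = grad(f)

    def q(gs: float, as_: float, gff: float, aff: float) -> float:
        if gs == 0.0 and gff == 0.0:
            rel = 0.0
        elif gs > gff:
            rel = gff / gs
        else:
            rel = gs / gff
        ang = 1.0 - abs(as_ - aff) / (np.pi / 2)
        qg = 0.9994 / (1.0 + np.exp(-15.0 * (rel - 0.5)))
        qa = 0.9879 / (1.0 + np.exp(-22.0 * (ang - 0.8)))
        return qg * qa

    num = 0.0
    den = 0.0
    h, w = a.shape
    for y in range(h):
        for x in range(w):
            num += q(ga[y, x], aa[y, x], gf[y, x], af[y, x]) * ga[y, x]
            num += q(gb[y, x], ab[y, x], gf[y, x], af[y, x]) * gb[y, x]
            den += ga[y, x] + gb[y, x]
    return num / den if den > 0 else 0.0


def _log_gabor_filters_oracle(shape):
    """Independent construction of the 4x4 log-Gabor bank (fftshifted grid)."""
    rows, cols = shape
    y = (np.arange(rows) - rows // 2) / rows
    x = (np.arange(cols) - cols // 2) / cols
    yy, xx = np.meshgrid(y, x, indexing="ij")
    radius = np.hypot(xx, yy)
    radius[rows // 2, cols // 2] = 1.0
    theta = np.arctan2(-yy, xx)
    lp = 1.0 / (1.0 + (radius / 0.45) ** 30)
    filters = []
    sigma_theta = np.pi / 4 / 1.2
    for o in range(4):
        ang = o * np.pi / 4
        d = np.arctan2(
            np.sin(theta) * np.cos(ang) - np.cos(theta) * np.sin(ang),
            np.cos(theta) * np.cos(ang) + np.sin(theta) * np.sin(ang),
        )
        spread = np.exp(-(np.abs(d) ** 2) / (2 * sigma_theta**2))
        row = []
        for s in range(4):
            f0 = 1.0 / (6.0 * 2.0**s)
            g = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(0.55) ** 2)) * lp
            g[rows // 2, cols // 2] = 0.0
            row.append(np.fft.ifftshift(g * spread))
        filters.append(row)
    return filters


def pc_oracle(gray: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Independent phase-congruency map (energy over amplitude, 4x4 bank)."""
    F = np.fft.fft2(gray)
    e_tot = np.zeros_like(gray, dtype=float)
    a_tot = np.zeros_like(gray, dtype=float)
    for scales in _log_gabor_filters_oracle(gray.shape):
        re = np.zeros_like(e_tot)
        im = np.zeros_like(e_tot)
        an = np.zeros_like(e_tot)
        for filt in scales:
            r = np.fft.ifft2(F * filt)
            re += r.real
            im += r.imag
            an += np.abs(r)
        e_tot += np.hypot(re, im)
        a_tot += an
    return e_tot / (a_tot + eps)


_SCHARR = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=float) / 16.0


def fsim_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Independent FSIM evaluation on 2-D luminance arrays."""
    pc1, pc2 = pc_oracle(a), pc_oracle(b)
    g1 = np.hypot(conv_oracle(a * 255.0, _SCHARR), conv_oracle(a * 255.0, _SCHARR.T))
    g2 = np.hypot(conv_oracle(b * 255.0, _SCHARR), conv_oracle(b * 255.0, _SCHARR.T))
    s_pc = (2 * pc1 * pc2 + 0.85) / (pc1**2 + pc2**2 + 0.85)
    s_g = (2 * g1 * g2 + 160.0) / (g1**2 + g2**2 + 160.0)
    pcm = np.maximum(pc1, pc2)
    return float((s_pc * s_g * pcm).sum() / pcm.sum())


def _conv_mirror(img: np.ndarray, kern: np.ndarray) -> np.ndarray:
    r = kern.shape[0] // 2
    padded = np.pad(img, r, mode="reflect")  # np 'reflect' = mirror, no edge repeat
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            out[y, x] = float((padded[y : y + 2 * r + 1, x : x + 2 * r + 1] * kern).sum())
    return out


def reduce_oracle(x: np.ndarray) -> np.ndarray:
    tap = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    return _conv_mirror(x, np.outer(tap, tap))[::2, ::2]


def expand_oracle(x: np.ndarray, shape) -> np.ndarray:
    tap = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    up = np.zeros(shape)
    up[::2, ::2] = x
    return _conv_mirror(up, np.outer(tap, tap) * 4.0)


def lpg_fuse_oracle(a: np.ndarray, b: np.ndarray, levels: int) -> np.ndarray:
    """Independent pyramid build / merge / collapse on 2-D arrays whose sides
    are multiples of 2**levels."""
    def pyramid(x):
        g = [x]
        for _ in range(levels):
            g.append(reduce_oracle(g[-1]))
        lap = [g[i] - expand_oracle(g[i + 1], g[i].shape) for i in range(levels)]
        lap.append(g[-1])
        return lap

    la, lb = pyramid(a), pyramid(b)
    fused = [np.where(np.abs(x) >= np.abs(y), x, y) for x, y in zip(la[:-1], lb[:-1])]
    fused.append((la[-1] + lb[-1]) / 2.0)
    x = fused[-1]
    for band in reversed(fused[:-1]):
        x = expand_oracle(x, band.shape) + band
    return x
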