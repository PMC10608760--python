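"""Fusion quality metrics: PSNR, SSIM, entropy, FSIM, and edge-based similarity.

Fusion has no ground truth: the fused image is compared against *both*
sources.  Reference-based scores (PSNR, SSIM, FSIM) are therefore computed
against each source separately and reported per-reference, with the
two-source mean as the headline value.  Entropy needs no reference, and the
edge-based similarity (the Xydeas-Petrovic Q^AB/F index) is jointly defined
over both sources by construction.

All reference-based metrics operate on channel-averaged (luminance) images,
avoiding color-space arbitrariness between a grayscale MRI and an RGB PET.
Every constant is pinned here and echoed in ``MetricsReport.params``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .image_io import Image, to_multichannel

__all__ = [
    "MetricsReport",
    "psnr",
    "ssim",
    "entropy",
    "fsim",
    "phase_congruency",
    "ebs",
    "evaluate_fusion",
]

# Xydeas-Petrovic sigmoid constants (strength / orientation preservation)
EBS_GAMMA_G = 0.9994
EBS_KAPPA_G = -15.0
EBS_SIGMA_G = 0.5
EBS_GAMMA_A = 0.9879
EBS_KAPPA_A = -22.0
EBS_SIGMA_A = 0.8

# FSIM stabilizers: T1 on phase congruency, T2 on a 0-255 gradient scale
FSIM_T1 = 0.85
FSIM_T2 = 160.0


@dataclass(frozen=True)
class MetricsReport:
    """The five quality scores for one fused image.

    ``psnr_db``, ``ssim``, ``fsim`` are two-source means; the per-source
    values live in ``per_reference['vs_mri' | 'vs_pet']``.
    """

    psnr_db: float
    ssim: float
    entropy_bits: float
    fsim: float
    ebs: float
    per_reference: dict[str, dict[str, float]]
    params: dict[str, object] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        """Flat headline scores, in the conventional column order."""
        return {
            "psnr": self.psnr_db,
            "ssim": self.ssim,
            "e": self.entropy_bits,
            "fsim": self.fsim,
            "ebs": self.ebs,
        }


def _luma(img: Image) -> np.ndarray:
    return to_multichannel(img, 1).pixels[:, :, 0]


def _check_shapes(*imgs: Image) -> None:
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"images must share a spatial shape, got {shapes}")


def psnr(ref: Image, test: Image, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in decibels.

    MSE is the mean squared per-pixel-per-channel difference after channel
    harmonization.  Identical images return ``inf``.
    """
    _check_shapes(ref, test)
    if peak <= 0:
        raise ValueError("peak must be positive")
    n = max(ref.channels, test.channels)
    a = to_multichannel(ref, n).pixels
    b = to_multichannel(test, n).pixels
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(ref: Image, test: Image) -> float:
    """Mean structural similarity over 11x11 Gaussian windows (sigma 1.5).

    Standard formulation with stabilizers ``C1=(0.01 L)^2``, ``C2=(0.03 L)^2``
    at dynamic range ``L=1``; color inputs are collapsed to luminance first.
    For images narrower than 11 pixels the window shrinks to the largest odd
    size that fits.
    """
    _check_shapes(ref, test)
    a, b = _luma(ref), _luma(test)
    m = min(a.shape)
    if m < 8:
        raise ValueError("ssim needs images at least 8 pixels per side")
    win = min(11, m if m % 2 else m - 1)
    return float(
        structural_similarity(
            a,
            b,
            win_size=win,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=1.0,
        )
    )


def entropy(img: Image, bins: int = 256) -> float:
    """Shannon entropy, in bits, of the luminance histogram.

    The channel-averaged image is quantized to ``bins`` equal-width levels on
    [0, 1]; empty bins are excluded.  Bounded above by ``log2(bins)``.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, _ = np.histogram(_luma(img), bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


# --------------------------------------------------------------------------
# FSIM: phase-congruency weighted feature similarity
# --------------------------------------------------------------------------


def _log_gabor_bank(
    shape: tuple[int, int],
    n_scales: int = 4,
    n_orient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
) -> list[list[np.ndarray]]:
    """Frequency-domain log-Gabor filters, indexed [orientation][scale]."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0) at DC; filter value there is zeroed below
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    # gentle low-pass keeps the filters from wrapping at the Nyquist boundary
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    bank: list[list[np.ndarray]] = []
    theta_sigma = np.pi / n_orient / 1.2
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        scales = []
        for s in range(n_scales):
            f0 = 1.0 / (min_wavelength * mult**s)
            log_gabor = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_onf) ** 2))
            log_gabor *= lowpass
            log_gabor[0, 0] = 0.0
            scales.append(log_gabor * spread)
        bank.append(scales)
    return bank


def phase_congruency(gray: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Phase congruency map of a 2-D array via a 4-scale, 4-orientation
    log-Gabor bank.

    Computed as total local energy over total local amplitude, summed over
    orientations; values in [0, 1], high where Fourier components align in
    phase (edges, lines) regardless of contrast.  No noise-threshold
    compensation is applied, keeping the map deterministic.
    """
    gray = np.asarray(gray, dtype=np.float64)
    F = np.fft.fft2(gray)
    bank = _log_gabor_bank(gray.shape)
    energy_total = np.zeros_like(gray)
    amplitude_total = np.zeros_like(gray)
    for scales in bank:
        sum_re = np.zeros_like(gray)
        sum_im = np.zeros_like(gray)
        sum_an = np.zeros_like(gray)
        for filt in scales:
            resp = np.fft.ifft2(F * filt)
            sum_re += resp.real
            sum_im += resp.imag
            sum_an += np.abs(resp)
        energy_total += np.sqrt(sum_re**2 + sum_im**2)
        amplitude_total += sum_an
    return energy_total / (amplitude_total + eps)


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0


def _scharr_magnitude(gray: np.ndarray) -> np.ndarray:
    gx = ndimage.correlate(gray, _SCHARR_X, mode="reflect")
    gy = ndimage.correlate(gray, _SCHARR_X.T, mode="reflect")
    return np.sqrt(gx**2 + gy**2)


def fsim(ref: Image, test: Image) -> float:
    """Feature similarity index on channel-averaged images, in [0, 1].

    Per-pixel similarity is the product of a phase-congruency term
    ``(2 PC1 PC2 + T1)/(PC1^2 + PC2^2 + T1)`` and a gradient term
    ``(2 G1 G2 + T2)/(G1^2 + G2^2 + T2)`` (Scharr magnitude on a 0-255
    scale), pooled with the pointwise-maximum phase congruency as salience
    weight.  Requires at least 32 pixels per side for the log-Gabor bank.
    """
    _check_shapes(ref, test)
    a, b = _luma(ref), _luma(test)
    if min(a.shape) < 32:
        raise ValueError("fsim needs images at least 32 pixels per side")
    pc1, pc2 = phase_congruency(a), phase_congruency(b)
    g1, g2 = _scharr_magnitude(a * 255.0), _scharr_magnitude(b * 255.0)
    s_pc = (2 * pc1 * pc2 + FSIM_T1) / (pc1**2 + pc2**2 + FSIM_T1)
    s_g = (2 * g1 * g2 + FSIM_T2) / (g1**2 + g2**2 + FSIM_T2)
    pcm = np.maximum(pc1, pc2)
    return float((s_pc * s_g * pcm).sum() / pcm.sum())


# --------------------------------------------------------------------------
# EBS: Xydeas-Petrovic edge-transfer index Q^AB/F
# --------------------------------------------------------------------------

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)


def _sobel_strength_orientation(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = ndimage.correlate(gray, _SOBEL_X, mode="reflect")
    sy = ndimage.correlate(gray, _SOBEL_X.T, mode="reflect")
    g = np.sqrt(sx**2 + sy**2)
    # orientation folded to (-pi/2, pi/2], the atan(sy/sx) convention
    alpha = np.mod(np.arctan2(sy, sx) + np.pi / 2, np.pi) - np.pi / 2
    return g, alpha


def _edge_preservation(
    g_src: np.ndarray, a_src: np.ndarray, g_fus: np.ndarray, a_fus: np.ndarray
) -> np.ndarray:
    """Per-pixel Q^XF: how well the fused image keeps X's edge strength and
    orientation, each mapped through the standard sigmoid."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(g_src > g_fus, g_fus / g_src, g_src / g_fus)
    rel = np.nan_to_num(rel, nan=0.0, posinf=0.0)  # both-zero gradients -> 0
    ang = 1.0 - np.abs(a_src - a_fus) / (np.pi / 2)
    q_g = EBS_GAMMA_G / (1.0 + np.exp(EBS_KAPPA_G * (rel - EBS_SIGMA_G)))
    q_a = EBS_GAMMA_A / (1.0 + np.exp(EBS_KAPPA_A * (ang - EBS_SIGMA_A)))
    return q_g * q_a


def ebs(src_a: Image, src_b: Image, fused: Image) -> float:
    """Edge-based similarity Q^AB/F of a fused image given both sources.

    Sobel gradient strength and orientation are extracted from each image;
    relative strength and orientation preservation pass through sigmoids with
    the standard constants; the per-source preservation maps are pooled with
    the source gradient strengths as weights.  Returns 0 when neither source
    contains any gradient.
    """
    _check_shapes(src_a, src_b, fused)
    ga, aa = _sobel_strength_orientation(_luma(src_a))
    gb, ab = _sobel_strength_orientation(_luma(src_b))
    gf, af = _sobel_strength_orientation(_luma(fused))
    q_af = _edge_preservation(ga, aa, gf, af)
    q_bf = _edge_preservation(gb, ab, gf, af)
    denom = float((ga + gb).sum())
    if denom == 0.0:
        return 0.0
    return float((q_af * ga + q_bf * gb).sum() / denom)


def evaluate_fusion(
    mri: Image,
    pet: Image,
    fused: Image,
    *,
    entropy_bins: int = 256,
    psnr_peak: float = 1.0,
    skip_fsim: bool = False,
) -> MetricsReport:
    """Score one fused image against its two sources.

    Entropy is computed on the fused image alone; PSNR, SSIM and FSIM against
    each source with the two-source mean as headline; EBS jointly.  With
    ``skip_fsim`` the FSIM slots hold NaN (for images below the 32-pixel
    log-Gabor minimum).
    """
    _check_shapes(mri, pet, fused)
    per: dict[str, dict[str, float]] = {}
    for name, src in (("vs_mri", mri), ("vs_pet", pet)):
        scores = {
            "psnr": psnr(src, fused, psnr_peak),
            "ssim": ssim(src, fused),
        }
        scores["fsim"] = math.nan if skip_fsim else fsim(src, fused)
        per[name] = scores

    def _mean(key: str) -> float:
        return (per["vs_mri"][key] + per["vs_pet"][key]) / 2.0

    return MetricsReport(
        psnr_db=_mean("psnr"),
        ssim=_mean("ssim"),
        entropy_bits=entropy(fused, entropy_bins),
        fsim=_mean("fsim"),
        ebs=ebs(mri, pet, fused),
        per_reference=per,
        params={
            "entropy_bins": entropy_bins,
            "psnr_peak": psnr_peak,
            "ssim_window": 11,
            "ssim_sigma": 1.5,
            "fsim_t1": FSIM_T1,
            "fsim_t2": FSIM_T2,
            "ebs_constants": {
                "gamma_g": EBS_GAMMA_G,
                "kappa_g": EBS_KAPPA_G,
                "sigma_g": EBS_SIGMA_G,
                "gamma_a": EBS_GAMMA_A,
                "kappa_a": EBS_KAPPA_A,
                "sigma_a": EBS_SIGMA_A,
            },
        },
    )
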