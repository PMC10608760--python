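"""Laplace sharpening of the source images.

Each source image is pre-blurred with a fixed 3x3 Gaussian kernel, the blurred
image is passed through a 3x3 Laplacian high-pass kernel, and the resulting
detail layer is added back to the *original* image scaled by an enhancement
factor ``k``, with the result clipped to [0, 1]:

    sharpened = clip(source + k * laplacian(gaussian(source)), 0, 1)

Two Laplacian variants are provided.  The ``standard`` variant is the usual
zero-sum high-pass matrix (all off-center entries -1, center +8, scaled by
1/16); zero sum guarantees that constant regions are left untouched.  The
``as_printed`` variant keeps a +1 in the bottom-right corner (sum 2/16) and
exists purely so the exact published matrix can be reproduced; it is almost
certainly a typographical slip in its source and is not the default.

Both kernels are applied as correlation (no kernel flip), matching the
``S(x+i, y+j) * K(i, j)`` index pattern of the defining sums.  For the
symmetric Gaussian the distinction is moot; it matters only for asymmetric
kernels such as ``as_printed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import Image

__all__ = [
    "Kernel",
    "SharpenParams",
    "gaussian_kernel",
    "laplacian_kernel",
    "convolve2d",
    "laplace_sharpen",
]


@dataclass(frozen=True)
class Kernel:
    """A small square correlation kernel of odd side length ``2*radius + 1``."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("kernel weights must be a square matrix")
        if w.shape[0] % 2 == 0:
            raise ValueError("kernel side length must be odd")
        if not np.all(np.isfinite(w)):
            raise ValueError("kernel weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def radius(self) -> int:
        return self.weights.shape[0] // 2


@dataclass(frozen=True)
class SharpenParams:
    """Tunables of the sharpening stage.

    ``enhancement_factor`` scales the Laplacian detail layer added back to the
    source (0 disables sharpening entirely).  ``border_mode`` chooses how the
    convolutions treat pixels beyond the image border: ``reflect`` (default)
    avoids the dark halo that zero padding produces at the frame.
    """

    enhancement_factor: float = 1.0
    laplacian_variant: str = "standard"
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.enhancement_factor < 0:
            raise ValueError("enhancement_factor must be >= 0")
        if self.laplacian_variant not in ("standard", "as_printed"):
            raise ValueError(f"unknown laplacian_variant {self.laplacian_variant!r}")
        if self.border_mode not in ("reflect", "zero"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")


def gaussian_kernel() -> Kernel:
    """The fixed 3x3 binomial Gaussian blur kernel (1/16)[[1,2,1],[2,4,2],[1,2,1]]."""
    return Kernel(np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]]) / 16.0)


def laplacian_kernel(variant: str = "standard") -> Kernel:
    """The 3x3 Laplacian high-pass kernel.

    ``standard``: (1/16)[[-1,-1,-1],[-1,8,-1],[-1,-1,-1]], zero-sum.
    ``as_printed``: same but with bottom-right entry +1/16 (sum 2/16),
    kept only for literal reproduction of the published matrix.
    """
    if variant == "standard":
        w = np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]]) / 16.0
    elif variant == "as_printed":
        w = np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, 1]]) / 16.0
    else:
        raise ValueError(f"unknown laplacian variant {variant!r}")
    return Kernel(w)


_NDIMAGE_MODE = {"reflect": "reflect", "zero": "constant"}


def convolve2d(
    img: Image | np.ndarray, kern: Kernel, border_mode: str = "reflect"
) -> np.ndarray:
    """Per-channel 2-D correlation of an image with a kernel.

    Accepts an :class:`Image` or a raw ``(H, W)`` / ``(H, W, C)`` array and
    returns a float array of the same shape.  The output is *not* clipped and
    may leave [0, 1]; clipping is the caller's responsibility.
    """
    if border_mode not in _NDIMAGE_MODE:
        raise ValueError(f"unknown border_mode {border_mode!r}")
    px = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    squeeze = px.ndim == 2
    if squeeze:
        px = px[:, :, np.newaxis]
    h, w, _ = px.shape
    if kern.radius > min(h, w) / 2:
        raise ValueError(
            f"kernel radius {kern.radius} too large for {h}x{w} image"
        )
    mode = _NDIMAGE_MODE[border_mode]
    out = np.empty_like(px)
    for c in range(px.shape[2]):
        ndimage.correlate(px[:, :, c], kern.weights, output=out[:, :, c], mode=mode, cval=0.0)
    return out[:, :, 0] if squeeze else out


def laplace_sharpen(img: Image, params: SharpenParams | None = None) -> Image:
    """Sharpen an image by adding its blur-then-Laplacian detail layer.

    Returns an image of the same shape, channel count and modality, clipped
    to [0, 1].  With ``enhancement_factor=0`` the input is returned unchanged;
    with the ``standard`` variant, constant images are exact fixed points.
    """
    params = params or SharpenParams()
    blurred = convolve2d(img, gaussian_kernel(), params.border_mode)
    lap = convolve2d(blurred, laplacian_kernel(params.laplacian_variant), params.border_mode)
    sharp = np.clip(img.pixels + params.enhancement_factor * lap, 0.0, 1.0)
    return img.with_pixels(sharp)
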