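"""Image container, loading, channel conversion, resizing, and PNG output.

All pipeline stages operate on :class:`Image`: a float array in the unit
interval ``[0, 1]``, shaped ``(height, width, channels)`` with 1 (grayscale)
or 3 (RGB) channels, tagged with the acquisition modality.  The unit-interval
convention is fixed package-wide because the sharpening stage clips to
``[0, 1]``; metrics that are conventionally defined on a 0-255 dynamic range
rescale internally and say so in their docstrings.

Coordinates are ``(row, column) = (y, x)``, 0-based, origin at the top-left,
matching raster file formats.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

__all__ = [
    "Modality",
    "Image",
    "load_image",
    "to_multichannel",
    "resize_to_match",
    "save_image",
]

#: ITU-R BT.601 luminance weights used for RGB -> grayscale collapse.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MIN_SIZE = 8  # smallest height/width the windowed metrics can handle


class Modality(str, enum.Enum):
    """Acquisition modality tag carried by every image."""

    MRI = "MRI"
    PET = "PET"
    FUSED = "FUSED"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Image:
    """A 2-D raster with pixel values in [0, 1].

    Parameters
    ----------
    pixels
        Array of shape ``(height, width, channels)``, dtype float64,
        all values finite and within ``[0, 1]``.
    modality
        Which modality the raster represents.
    """

    pixels: np.ndarray
    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3:
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={px.ndim}")
        if px.shape[2] not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {px.shape[2]}")
        if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
            raise ValueError(
                f"image must be at least {MIN_SIZE}x{MIN_SIZE}, got "
                f"{px.shape[0]}x{px.shape[1]}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(height, width)``."""
        return self.pixels.shape[:2]

    def with_pixels(self, pixels: np.ndarray, modality: Modality | None = None) -> "Image":
        """Return a copy with new pixel data (and optionally a new modality)."""
        return Image(pixels, self.modality if modality is None else modality)


def load_image(
    path: str | Path,
    force_modality: Modality | str = Modality.OTHER,
    *,
    nifti_slice: int | None = None,
) -> Image:
    """Load a raster file (PNG/JPEG/TIFF, optionally single-slice NIfTI).

    Integer pixel data are rescaled to [0, 1] by the format's maximum
    representable value (255 for 8-bit, 65535 for 16-bit).  Grayscale files
    yield ``channels=1``, color files ``channels=3``; an alpha channel is
    dropped.

    Parameters
    ----------
    path
        File to read.
    force_modality
        Modality tag to attach to the result.
    nifti_slice
        For NIfTI volumes, the axial slice index to extract (default:
        middle slice).  Ignored for raster formats.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return _load_nifti_slice(path, force_modality, nifti_slice)
    try:
        with PILImage.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA"):
                im = im.convert("RGB" if im.mode == "RGBA" else "L")
            if im.mode == "P":
                im = im.convert("RGB")
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.dtype == np.uint8:
        px = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        px = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        px = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")
    return Image(px, Modality(force_modality))


def _load_nifti_slice(
    path: Path, force_modality: Modality | str, slice_index: int | None
) -> Image:
    """Read one axial slice of a NIfTI volume, min-max scaled to [0, 1]."""
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - nibabel is an extra
        raise ImportError("NIfTI support requires the 'nibabel' package") from exc
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim == 2:
        sl = vol
    else:
        vol = vol.reshape(vol.shape[:3])
        k = vol.shape[2] // 2 if slice_index is None else slice_index
        sl = vol[:, :, k]
    lo, hi = sl.min(), sl.max()
    px = np.zeros_like(sl) if hi <= lo else (sl - lo) / (hi - lo)
    return Image(px, Modality(force_modality))


def to_multichannel(img: Image, n: int) -> Image:
    """Convert between 1- and 3-channel representations.

    1 -> 3 replicates the single channel; 3 -> 1 takes the luminance
    combination ``0.299 R + 0.587 G + 0.114 B``; matching counts are
    returned unchanged.
    """
    if n not in (1, 3):
        raise ValueError(f"target channel count must be 1 or 3, got {n}")
    if img.channels == n:
        return img
    if n == 3:
        return img.with_pixels(np.repeat(img.pixels, 3, axis=2))
    luma = img.pixels @ LUMA_WEIGHTS
    return img.with_pixels(np.clip(luma, 0.0, 1.0))


def _bilinear_resize(px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Aligned-corners bilinear resampling of an (H, W, C) array."""
    h, w, _ = px.shape
    nh, nw = shape
    ys = np.linspace(0.0, h - 1.0, nh)
    xs = np.linspace(0.0, w - 1.0, nw)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0)[:, None, None]
    fx = (xs - x0)[None, :, None]
    top = px[y0][:, x0] * (1 - fx) + px[y0][:, x1] * fx
    bot = px[y1][:, x0] * (1 - fx) + px[y1][:, x1] * fx
    return top * (1 - fy) + bot * fy


def resize_image(img: Image, shape: tuple[int, int]) -> Image:
    """Resample an image to ``shape=(height, width)`` by bilinear interpolation."""
    if img.shape == tuple(shape):
        return img
    return img.with_pixels(np.clip(_bilinear_resize(img.pixels, tuple(shape)), 0.0, 1.0))


def resize_to_match(a: Image, b: Image) -> tuple[Image, Image]:
    """Harmonize the spatial shapes of two co-registered images.

    If shapes already agree the inputs are returned unchanged; otherwise the
    smaller image is upsampled to the larger's ``height x width``.  No spatial
    registration is attempted: inputs are assumed co-registered upstream.
    """
    if a.shape == b.shape:
        return a, b
    target = (max(a.height, b.height), max(a.width, b.width))
    return resize_image(a, target), resize_image(b, target)


def save_image(img: Image, path: str | Path) -> None:
    """Write an image as 8-bit PNG (values scaled by 255, rounded half-up).

    Round-tripping through :func:`load_image` reproduces each pixel within
    half a quantization step, 1/510.
    """
    # np.floor(x + 0.5) is round-half-up; np.round would round half-to-even
    q = np.floor(img.pixels * 255.0 + 0.5).astype(np.uint8)
    if q.shape[2] == 1:
        q = q[:, :, 0]
    PILImage.fromarray(q).save(Path(path), format="PNG")
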