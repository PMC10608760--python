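"""Shallow convolutional feature extraction and upsampling.

The fusion method is training-free: feature maps come from a single bank of
first-layer convolution filters applied to each (sharpened) source image,
followed by rectification.  The maps are then upsampled with *transposed
convolution* — a fractionally-strided scatter-and-sum that multiplies spatial
resolution by the stride — run once per kernel size so that several receptive
-field scales contribute, and the branch outputs are merged element-wise.
Finally each channel is standardized by parameter-free instance
normalization (zero spatial mean, unit spatial variance, no learned scale or
shift), which removes intensity/contrast/scale differences between the two
modalities before they compete in the maximum-fusion stage.

Filter banks are pluggable via :class:`BackboneSpec`:

* ``seeded_random`` (default) draws He-scaled zero-mean Gaussian filters from
  a fixed seed, making the whole pipeline deterministic and self-contained.
  Because every feature map is instance-normalized before fusion, the fusion
  decision depends on relative spatial activation patterns, not on any
  particular trained weights.
* ``pretrained_layer1`` loads the first convolution layer of the standard
  19-layer VGG backbone when torch/torchvision and its weights are
  installed; otherwise it raises an explicit error naming the fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import Image, Modality

__all__ = [
    "FeatureMap",
    "BackboneSpec",
    "TransposeSpec",
    "BackboneWeightsError",
    "extract_layer1_features",
    "transposed_convolve",
    "multi_scale_transpose",
    "instance_normalize",
    "bilinear_kernel_1d",
]

logger = logging.getLogger(__name__)


class BackboneWeightsError(RuntimeError):
    """Raised when pretrained backbone weights cannot be loaded."""


@dataclass(frozen=True)
class FeatureMap:
    """Multi-channel spatial activations, shaped ``(channels, height, width)``.

    ``scale`` is the resolution multiplier relative to the source image
    (1 straight after extraction, multiplied by the stride at each
    transposed-convolution pass).
    """

    values: np.ndarray
    modality: Modality = Modality.OTHER
    scale: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"feature values must be 3-D (C, H, W), got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]

    @property
    def width(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class BackboneSpec:
    """Which filter bank produces the layer-1 features."""

    kind: str = "seeded_random"
    out_channels: int = 64
    filter_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("seeded_random", "pretrained_layer1"):
            raise ValueError(f"unknown backbone kind {self.kind!r}")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.filter_size < 1 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be odd and positive")


@dataclass(frozen=True)
class TransposeSpec:
    """Multi-kernel transposed-convolution settings.

    One upsampling branch runs per entry of ``kernel_sizes`` (all with the
    same ``stride``); branch outputs share a shape by the symmetric-cropping
    contract and are merged element-wise by ``combine``.
    """

    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    stride: int = 2
    combine: str = "mean"
    kernel_fill: str = "bilinear"

    def __post_init__(self) -> None:
        sizes = tuple(int(k) for k in self.kernel_sizes)
        if not sizes:
            raise ValueError("kernel_sizes must not be empty")
        if any(k < 1 or k % 2 == 0 for k in sizes):
            raise ValueError("all kernel sizes must be odd and positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.combine not in ("mean", "max"):
            raise ValueError(f"unknown combine {self.combine!r}")
        if self.kernel_fill not in ("bilinear", "ones"):
            raise ValueError(f"unknown kernel_fill {self.kernel_fill!r}")
        object.__setattr__(self, "kernel_sizes", sizes)


def _he_filters(spec: BackboneSpec, in_channels: int) -> np.ndarray:
    """Fixed-seed zero-mean Gaussian filters with variance 2/fan_in."""
    fan_in = in_channels * spec.filter_size**2
    rng = np.random.default_rng(spec.seed)
    return rng.normal(
        0.0,
        np.sqrt(2.0 / fan_in),
        size=(spec.out_channels, in_channels, spec.filter_size, spec.filter_size),
    )


def _pretrained_filters(spec: BackboneSpec) -> np.ndarray:
    try:
        import torchvision  # noqa: F401
        from torchvision.models import VGG19_Weights, vgg19
    except ImportError as exc:
        raise BackboneWeightsError(
            "pretrained_layer1 requires torch/torchvision with downloaded "
            "weights; use BackboneSpec(kind='seeded_random') for a fully "
            "offline, deterministic filter bank"
        ) from exc
    try:
        model = vgg19(weights=VGG19_Weights.IMAGENET1K_V1)
    except Exception as exc:  # weight download/cache failure
        raise BackboneWeightsError(
            "could not load pretrained VGG19 layer-1 weights; use "
            "BackboneSpec(kind='seeded_random') instead"
        ) from exc
    return model.features[0].weight.detach().numpy().astype(np.float64)


def extract_layer1_features(img: Image, spec: BackboneSpec | None = None) -> FeatureMap:
    """Apply one bank of filters (same-padding, stride 1) plus rectification.

    The input must have 3 channels (use :func:`~neurofuse.image_io.to_multichannel`
    first).  Output is a :class:`FeatureMap` at scale 1 with
    ``spec.out_channels`` channels.
    """
    spec = spec or BackboneSpec()
    if img.channels != 3:
        raise ValueError("feature extraction expects a 3-channel image")
    if spec.kind == "pretrained_layer1":
        filters = _pretrained_filters(spec)
        if filters.shape[-1] != spec.filter_size:
            filters = filters  # pretrained bank fixes its own 3x3 size
    else:
        filters = _he_filters(spec, in_channels=3)
    px = img.pixels  # (H, W, 3)
    out = np.zeros((filters.shape[0], img.height, img.width))
    # same-padding convolution-layer convention: zeros beyond the border
    for o in range(filters.shape[0]):
        acc = out[o]
        for ci in range(filters.shape[1]):
            acc += ndimage.correlate(px[:, :, ci], filters[o, ci], mode="constant", cval=0.0)
    np.maximum(out, 0.0, out=out)  # ReLU
    return FeatureMap(out, modality=img.modality, scale=1)


def bilinear_kernel_1d(size: int) -> np.ndarray:
    """Triangle profile of the given size: 1 at the center, tapering linearly."""
    c = (size - 1) / 2.0
    i = np.arange(size)
    return 1.0 - np.abs(i - c) / (c + 1.0)


def _transpose_kernel(size: int, fill: str) -> np.ndarray:
    if fill == "ones":
        return np.ones((size, size))
    w = bilinear_kernel_1d(size)
    return np.outer(w, w)


def transposed_convolve(
    fmap: FeatureMap,
    kernel_size: int,
    stride: int = 2,
    kernel_fill: str = "bilinear",
) -> FeatureMap:
    """Fractionally-strided (transposed) convolution of each channel.

    Every input value scatters a ``kernel_size x kernel_size`` weighted copy
    of itself onto the output grid at stride-spaced anchor positions;
    overlapping contributions sum.  The raw scatter canvas has side
    ``stride*(n-1) + kernel_size``; it is cropped (or zero-padded, when the
    kernel is smaller than the stride) symmetrically to exactly
    ``stride*height x stride*width``, so branches with different kernel sizes
    align element-wise.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    if kernel_fill == "ones" and kernel_size < stride:
        logger.warning(
            "ones-filled kernel of size %d with stride %d leaves coverage gaps",
            kernel_size,
            stride,
        )
    kern = _transpose_kernel(kernel_size, kernel_fill)
    c, h, w = fmap.values.shape
    full_h = stride * (h - 1) + kernel_size
    full_w = stride * (w - 1) + kernel_size
    full = np.zeros((c, full_h, full_w))
    vals = fmap.values
    for a in range(kernel_size):
        for b in range(kernel_size):
            full[:, a : a + stride * (h - 1) + 1 : stride,
                 b : b + stride * (w - 1) + 1 : stride] += vals * kern[a, b]
    out = _center_fit(full, stride * h, stride * w)
    return FeatureMap(out, modality=fmap.modality, scale=fmap.scale * stride)


def _center_fit(arr: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Symmetrically crop or zero-pad the spatial dims of (C, H, W) to (th, tw)."""
    out = arr
    for axis, target in ((1, th), (2, tw)):
        n = out.shape[axis]
        if n > target:
            start = (n - target) // 2
            out = np.take(out, np.arange(start, start + target), axis=axis)
        elif n < target:
            before = (target - n) // 2
            pad = [(0, 0)] * out.ndim
            pad[axis] = (before, target - n - before)
            out = np.pad(out, pad)
    return out


def multi_scale_transpose(fmap: FeatureMap, spec: TransposeSpec | None = None) -> FeatureMap:
    """Run one transposed-convolution branch per kernel size and merge them.

    All branches share the stride, so the cropping contract gives them
    identical shapes; they are combined element-wise (mean by default, max
    optionally).  Channel count is preserved.
    """
    spec = spec or TransposeSpec()
    branches = [
        transposed_convolve(fmap, k, spec.stride, spec.kernel_fill).values
        for k in spec.kernel_sizes
    ]
    stacked = np.stack(branches)
    merged = stacked.mean(axis=0) if spec.combine == "mean" else stacked.max(axis=0)
    return FeatureMap(merged, modality=fmap.modality, scale=fmap.scale * spec.stride)


def instance_normalize(fmap: FeatureMap, eps: float = 1e-5) -> FeatureMap:
    """Standardize each channel over its spatial extent.

    For every channel independently, subtract the spatial mean and divide by
    the square root of the population spatial variance (divisor ``H*W``) plus
    ``eps``.  No learnable scale or shift is applied.  ``eps`` guards the
    zero-variance (constant-channel) case, which maps to all zeros.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    v = fmap.values
    mu = v.mean(axis=(1, 2), keepdims=True)
    var = v.var(axis=(1, 2), keepdims=True)  # population variance, /HW
    out = (v - mu) / np.sqrt(var + eps)
    return FeatureMap(out, modality=fmap.modality, scale=fmap.scale)
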