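"""Fusion of MRI and PET: the maximum-strategy pipeline and two baselines.

The proposed pipeline sharpens both sources, extracts upsampled
instance-normalized feature maps per modality, and merges the maps by the
pixel-wise *maximum strategy*: at every channel and position the fused feature
map keeps the larger of the two normalized activations, so the strongest
response from either modality survives.

Feature-space fusion still has to become a pixel-space image.  The
reconstruction used here follows the shallow-backbone fusion lineage: each
modality's feature map is collapsed to a per-pixel L1 *activity* (summed
absolute activation across channels, resampled to source resolution), the
activities drive a per-pixel decision weight — hard winner-take-all or a
softmax with temperature — and the fused pixel is the convex combination of
the two *sharpened* sources under that weight.  Soft weighting with
temperature 1 is the default; hard mode mirrors the maximum semantics
literally.

Baselines: multi-level discrete wavelet fusion (approximation coefficients
averaged, detail coefficients picked by larger magnitude), Laplacian-
Gaussian pyramid fusion (band-pass levels by max-abs, top level by mean),
and a naive pixel average as a control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .features import (
    BackboneSpec,
    FeatureMap,
    TransposeSpec,
    extract_layer1_features,
    instance_normalize,
    multi_scale_transpose,
)
from .image_io import Image, Modality, _bilinear_resize, resize_to_match, to_multichannel
from .sharpening import SharpenParams, laplace_sharpen

__all__ = [
    "WeightMap",
    "FusionConfig",
    "FusionResult",
    "max_fuse",
    "activity_map",
    "decision_weights",
    "fuse_proposed",
    "fuse_dwt",
    "fuse_lpg",
    "fuse_average",
    "fuse",
]


@dataclass(frozen=True)
class WeightMap:
    """Per-pixel MRI weight in [0, 1]; the PET weight is its complement."""

    values: np.ndarray
    mode: str = "soft"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("weight map must be 2-D")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FusionConfig:
    """Every tunable of the fusion pipeline in one place."""

    sharpen: SharpenParams = field(default_factory=SharpenParams)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    transpose: TransposeSpec = field(default_factory=TransposeSpec)
    eps: float = 1e-5
    weight_mode: str = "soft"
    softness: float = 1.0
    method: str = "proposed"
    dwt_levels: int = 2
    dwt_wavelet: str = "db2"
    lpg_levels: int = 2

    def __post_init__(self) -> None:
        if self.softness <= 0:
            raise ValueError("softness must be positive")
        if self.weight_mode not in ("hard", "soft"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.method not in ("proposed", "dwt", "lpg", "average"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class FusionResult:
    """Output of the proposed pipeline, with provenance.

    ``intermediates`` retains the per-modality normalized feature maps and
    the max-fused feature map; ``seed_log`` records every seed consumed.
    """

    fused: Image
    weight_map: WeightMap
    intermediates: dict[str, FeatureMap]
    config: FusionConfig
    seed_log: tuple[int, ...]


def max_fuse(f_mri: FeatureMap, f_pet: FeatureMap) -> FeatureMap:
    """Element-wise maximum of two aligned feature maps (the maximum strategy)."""
    if f_mri.values.shape != f_pet.values.shape:
        raise ValueError(
            f"shape mismatch: {f_mri.values.shape} vs {f_pet.values.shape}"
        )
    return FeatureMap(
        np.maximum(f_mri.values, f_pet.values),
        modality=Modality.FUSED,
        scale=f_mri.scale,
    )


def activity_map(fmap: FeatureMap) -> np.ndarray:
    """Collapse a feature map to per-pixel L1 activity at source resolution.

    Sums absolute activations across channels, then bilinearly resamples by
    the map's scale factor back to the source-image grid.  Nonnegative.
    """
    act = np.abs(fmap.values).sum(axis=0)
    if fmap.scale != 1:
        h, w = act.shape
        target = (h // fmap.scale, w // fmap.scale)
        act = _bilinear_resize(act[:, :, np.newaxis], target)[:, :, 0]
    return act


def decision_weights(
    a_mri: np.ndarray,
    a_pet: np.ndarray,
    mode: str = "soft",
    softness: float = 1.0,
) -> WeightMap:
    """Turn two activity maps into a per-pixel MRI weight.

    ``hard``: winner-take-all (1 where MRI activity is larger, 0 where
    smaller, 0.5 at exact ties).  ``soft``: two-way softmax of the activities
    at temperature ``softness``, computed stably; as softness -> 0 the soft
    weights converge to the hard ones away from ties.
    """
    a_mri = np.asarray(a_mri, dtype=np.float64)
    a_pet = np.asarray(a_pet, dtype=np.float64)
    if a_mri.shape != a_pet.shape:
        raise ValueError("activity maps must share a shape")
    if mode == "hard":
        w = np.where(a_mri > a_pet, 1.0, 0.0)
        w[a_mri == a_pet] = 0.5
        return WeightMap(w, mode="hard")
    if softness <= 0:
        raise ValueError("softness must be positive")
    # logistic of the activity difference: exp-normalized without overflow
    d = (a_mri - a_pet) / softness
    w = np.empty_like(d)
    pos = d >= 0
    w[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    w[~pos] = e / (1.0 + e)
    return WeightMap(w, mode="soft")


def _harmonize_channels(a: Image, b: Image) -> tuple[Image, Image]:
    """Broadcast grayscale to RGB when the partner image is RGB."""
    n = max(a.channels, b.channels)
    return to_multichannel(a, n), to_multichannel(b, n)


def _feature_branch(img: Image, config: FusionConfig) -> FeatureMap:
    """Sharpened image -> extracted, upsampled, normalized feature map."""
    f = extract_layer1_features(to_multichannel(img, 3), config.backbone)
    f = multi_scale_transpose(f, config.transpose)
    return instance_normalize(f, config.eps)


def fuse_proposed(mri: Image, pet: Image, config: FusionConfig | None = None) -> FusionResult:
    """Run the full maximum-strategy fusion pipeline on a co-registered pair.

    Both sources are Laplace-sharpened; per modality, features are extracted,
    upsampled by multi-kernel transposed convolution, and instance-
    normalized; the normalized maps are max-fused (kept in
    ``intermediates['fused']``); their L1 activities drive the per-pixel
    decision weights; and the fused pixel is the weighted combination of the
    sharpened sources, clipped to [0, 1].
    """
    config = config or FusionConfig()
    mri, pet = resize_to_match(mri, pet)
    mri_sharp = laplace_sharpen(mri, config.sharpen)
    pet_sharp = laplace_sharpen(pet, config.sharpen)

    f_mri = _feature_branch(mri_sharp, config)
    f_pet = _feature_branch(pet_sharp, config)
    fused_features = max_fuse(f_mri, f_pet)

    weights = decision_weights(
        activity_map(f_mri),
        activity_map(f_pet),
        mode=config.weight_mode,
        softness=config.softness,
    )

    mri_px, pet_px = _harmonize_channels(mri_sharp, pet_sharp)
    w = weights.values[:, :, np.newaxis]
    fused_px = np.clip(w * mri_px.pixels + (1.0 - w) * pet_px.pixels, 0.0, 1.0)
    return FusionResult(
        fused=Image(fused_px, Modality.FUSED),
        weight_map=weights,
        intermediates={"mri": f_mri, "pet": f_pet, "fused": fused_features},
        config=config,
        seed_log=(config.backbone.seed,),
    )


def _fuse_dwt_channel(
    a: np.ndarray, b: np.ndarray, levels: int, wavelet: str, low_rule: str
) -> np.ndarray:
    ca = pywt.wavedec2(a, wavelet, level=levels)
    cb = pywt.wavedec2(b, wavelet, level=levels)
    if low_rule == "mean":
        approx = (ca[0] + cb[0]) / 2.0
    else:  # max
        approx = np.maximum(ca[0], cb[0])
    fusedc = [approx]
    for da, db in zip(ca[1:], cb[1:]):
        fusedc.append(tuple(np.where(np.abs(x) >= np.abs(y), x, y) for x, y in zip(da, db)))
    rec = pywt.waverec2(fusedc, wavelet)
    return rec[: a.shape[0], : a.shape[1]]


def fuse_dwt(
    mri: Image,
    pet: Image,
    levels: int = 2,
    wavelet_name: str = "db2",
    low_rule: str = "mean",
    high_rule: str = "max_abs",
) -> Image:
    """Multi-level discrete-wavelet-transform fusion baseline.

    Per channel, both sources are decomposed to ``levels`` wavelet levels;
    approximation coefficients merge by ``low_rule`` (mean by default),
    detail coefficients by picking the larger-magnitude coefficient; the
    merged pyramid is inverse-transformed and clipped to [0, 1].
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if low_rule not in ("mean", "max"):
        raise ValueError(f"unknown low_rule {low_rule!r}")
    if high_rule != "max_abs":
        raise ValueError(f"unknown high_rule {high_rule!r}")
    mri, pet = resize_to_match(mri, pet)
    a, b = _harmonize_channels(mri, pet)
    max_level = pywt.dwtn_max_level(a.shape, wavelet_name)
    if levels > max_level:
        raise ValueError(
            f"image {a.shape} supports at most {max_level} '{wavelet_name}' levels"
        )
    out = np.empty_like(a.pixels)
    for c in range(a.channels):
        out[:, :, c] = _fuse_dwt_channel(
            a.pixels[:, :, c], b.pixels[:, :, c], levels, wavelet_name, low_rule
        )
    return Image(np.clip(out, 0.0, 1.0), Modality.FUSED)


_PYR_TAP = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _pyr_blur(x: np.ndarray, gain: float = 1.0) -> np.ndarray:
    from scipy import ndimage

    # mirror (no edge repeat) keeps constants exact through expand's
    # zero-stuffed grid: reflected samples land on the same stride phase
    y = ndimage.correlate1d(x, _PYR_TAP * gain, axis=0, mode="mirror")
    return ndimage.correlate1d(y, _PYR_TAP, axis=1, mode="mirror")


def _pyr_reduce(x: np.ndarray) -> np.ndarray:
    return _pyr_blur(x)[::2, ::2]


def _pyr_expand(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    up = np.zeros(shape)
    up[::2, ::2] = x
    return _pyr_blur(up, gain=4.0)  # x4 restores unit DC gain after zero-stuffing


def laplacian_pyramid(x: np.ndarray, levels: int) -> list[np.ndarray]:
    """Band-pass pyramid: ``levels`` difference layers plus the Gaussian top."""
    g = [x]
    for _ in range(levels):
        g.append(_pyr_reduce(g[-1]))
    lap = [g[i] - _pyr_expand(g[i + 1], g[i].shape) for i in range(levels)]
    lap.append(g[-1])
    return lap


def collapse_pyramid(lap: list[np.ndarray]) -> np.ndarray:
    x = lap[-1]
    for band in reversed(lap[:-1]):
        x = _pyr_expand(x, band.shape) + band
    return x


def fuse_lpg(mri: Image, pet: Image, levels: int = 2) -> Image:
    """Laplacian-Gaussian pyramid fusion baseline.

    Per channel: both sources are (reflect-)padded to a multiple of
    ``2**levels``, decomposed into Laplacian pyramids built with the 5-tap
    [1,4,6,4,1]/16 filter, merged band by band — max-abs selection on the
    band-pass levels, mean on the Gaussian top — collapsed, unpadded, and
    clipped to [0, 1].
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    mri, pet = resize_to_match(mri, pet)
    a, b = _harmonize_channels(mri, pet)
    h, w = a.shape
    block = 2**levels
    if min(h, w) < block:
        raise ValueError(f"{levels} pyramid levels need at least {block} pixels per side")
    ph = (-h) % block
    pw = (-w) % block
    out = np.empty_like(a.pixels)
    for c in range(a.channels):
        xa = np.pad(a.pixels[:, :, c], ((0, ph), (0, pw)), mode="reflect")
        xb = np.pad(b.pixels[:, :, c], ((0, ph), (0, pw)), mode="reflect")
        la = laplacian_pyramid(xa, levels)
        lb = laplacian_pyramid(xb, levels)
        fused = [np.where(np.abs(x) >= np.abs(y), x, y) for x, y in zip(la[:-1], lb[:-1])]
        fused.append((la[-1] + lb[-1]) / 2.0)
        out[:, :, c] = collapse_pyramid(fused)[:h, :w]
    return Image(np.clip(out, 0.0, 1.0), Modality.FUSED)


def fuse_average(mri: Image, pet: Image) -> Image:
    """Naive control: the per-pixel mean of the two (channel-harmonized) sources."""
    mri, pet = resize_to_match(mri, pet)
    a, b = _harmonize_channels(mri, pet)
    return Image((a.pixels + b.pixels) / 2.0, Modality.FUSED)


def fuse(mri: Image, pet: Image, config: FusionConfig | None = None) -> Image:
    """Dispatch on ``config.method`` and return the fused image."""
    config = config or FusionConfig()
    if config.method == "proposed":
        return fuse_proposed(mri, pet, config).fused
    if config.method == "dwt":
        return fuse_dwt(mri, pet, config.dwt_levels, config.dwt_wavelet)
    if config.method == "lpg":
        return fuse_lpg(mri, pet, config.lpg_levels)
    return fuse_average(mri, pet)
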