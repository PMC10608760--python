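"""Paired synthetic MRI-like / PET-like phantoms with known content.

The generator produces co-registered pairs whose information is
*complementary by construction*: the structural (pseudo-MRI) image carries
nested elliptical shells plus a patch of fine sinusoidal ridges (marked by
``edge_mask``), while the functional (pseudo-PET) image is a smoothed copy of
the anatomy — the ridges are blurred away — with a circular hotspot of
designed contrast (marked by ``hotspot_mask``) rendered through a fixed warm
colormap.  A good fused image must therefore keep the ridge texture from the
structural source *and* the hotspot from the functional source, which turns
fusion quality into assertable statistics: gradient energy inside
``edge_mask`` and mean intensity inside ``hotspot_mask``.

Everything is deterministic given the seed (single-stream integer-state
generator, no parallelism), and the two masks are disjoint by construction.
The generator does not attempt anatomical realism or modality physics
(no partial-volume effects, attenuation, or acquisition noise models beyond
additive Gaussian noise).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import Image, Modality

__all__ = [
    "PhantomConfig",
    "PhantomPair",
    "warm_colormap",
    "apply_colormap",
    "make_structural",
    "make_functional",
    "make_pair",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom pair.

    ``hotspot_contrast`` is the designed ratio of hotspot mean to background
    mean in the functional scalar map (before color rendering); with zero
    noise it is hit exactly.  Noise levels are standard deviations of
    additive Gaussian noise in [0, 1] intensity units.
    """

    size: int = 128
    n_ellipses: int = 3
    edge_amp: float = 0.25
    structural_noise_sd: float = 0.01
    hotspot_contrast: float = 2.0
    blur_sd: float = 2.0
    functional_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.hotspot_contrast < 1:
            raise ValueError("hotspot_contrast must be >= 1")


@dataclass(frozen=True)
class PhantomPair:
    """A co-registered pseudo-MRI / pseudo-PET pair with its design masks."""

    mri: Image
    pet: Image
    edge_mask: np.ndarray
    hotspot_mask: np.ndarray
    hotspot_contrast: float
    seed: int
    params: dict
    functional_scalar: np.ndarray  # pre-colormap PET intensity map

    def __post_init__(self) -> None:
        if self.mri.shape != self.pet.shape:
            raise ValueError("pair images must share a spatial shape")
        if np.any(self.edge_mask & self.hotspot_mask):
            raise ValueError("edge_mask and hotspot_mask must be disjoint")


def warm_colormap() -> np.ndarray:
    """Fixed 256-entry warm (black-red-yellow-white) lookup table.

    Piecewise-linear 'hot'-style ramp: red rises first, then green, then
    blue, so rendered luminance is monotone in the underlying scalar.
    """
    v = np.arange(256) / 255.0
    r = np.clip(3.0 * v, 0.0, 1.0)
    g = np.clip(3.0 * v - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * v - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=1)


_WARM_LUT = warm_colormap()


def apply_colormap(scalar: np.ndarray) -> np.ndarray:
    """Map a [0, 1] scalar field through the warm LUT to an (H, W, 3) array."""
    idx = np.clip(np.floor(scalar * 255.0 + 0.5).astype(int), 0, 255)
    return _WARM_LUT[idx]


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates normalized to [-1, 1] on both axes."""
    c = np.linspace(-1.0, 1.0, size)
    return np.meshgrid(c, c, indexing="ij")


def _edge_region(size: int) -> np.ndarray:
    """Disk on the left side of the brain reserved for the ridge texture."""
    yy, xx = _grid(size)
    return ((yy - 0.0) ** 2 + (xx + 0.38) ** 2) < 0.22**2


def _hotspot_region(size: int) -> np.ndarray:
    """Disk on the right side of the brain reserved for the hotspot."""
    yy, xx = _grid(size)
    return ((yy - 0.05) ** 2 + (xx - 0.38) ** 2) < 0.16**2


def make_structural(
    seed: int,
    size: int = 128,
    n_ellipses: int = 3,
    edge_amp: float = 0.25,
    noise_sd: float = 0.01,
) -> tuple[Image, np.ndarray]:
    """Generate a grayscale structural phantom and its edge-texture mask.

    A bright outer "skull" shell encloses a mid-gray "brain" with
    ``n_ellipses`` nested elliptical shells of seeded intensity and geometry;
    a left-hemisphere disk carries fine diagonal sinusoidal ridges of
    amplitude ``edge_amp`` (the ``edge_mask``); optional additive Gaussian
    noise; clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    yy, xx = _grid(size)
    img = np.zeros((size, size))

    r2 = yy**2 + (xx / 0.92) ** 2
    img[r2 < 0.95**2] = 0.85  # skull shell
    img[r2 < 0.86**2] = 0.45  # brain parenchyma

    for i in range(n_ellipses):
        ay = rng.uniform(0.15, 0.55)
        ax = rng.uniform(0.15, 0.55)
        cy = rng.uniform(-0.25, 0.25)
        cx = rng.uniform(-0.25, 0.25)
        level = rng.uniform(0.3, 0.7)
        shell = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
        ring = (shell < 1.0) & (shell > 0.75)
        img[ring] = level

    edge_mask = _edge_region(size)
    phase = rng.uniform(0.0, 2 * np.pi)
    ridges = np.sin(2 * np.pi * (yy + 0.6 * xx) * size / 8.0 + phase)
    img[edge_mask] = 0.45 + edge_amp * ridges[edge_mask]

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return Image(np.clip(img, 0.0, 1.0), Modality.MRI), edge_mask


def make_functional(
    structural: Image,
    seed: int,
    hotspot_contrast: float = 2.0,
    blur_sd: float = 2.0,
    noise_sd: float = 0.01,
) -> tuple[Image, np.ndarray, np.ndarray]:
    """Generate an RGB functional phantom from a structural layout.

    The structural image is Gaussian-blurred (losing the fine ridge texture),
    rescaled into a low-intensity metabolic background band, and a circular
    hotspot is set to ``hotspot_contrast`` times the background mean — exact
    in noise-free mode.  After optional noise the scalar map is rendered
    through the warm colormap.

    Returns ``(pet_image, hotspot_mask, scalar_map)``; the scalar map is the
    pre-colormap intensity field on which the contrast is defined.
    """
    if hotspot_contrast < 1:
        raise ValueError("hotspot_contrast must be >= 1")
    rng = np.random.default_rng(seed)
    gray = structural.pixels[:, :, 0]
    size = gray.shape[0]
    smooth = ndimage.gaussian_filter(gray, sigma=blur_sd, mode="reflect")

    lo, hi = 0.08, 0.45  # metabolic background band
    rng_span = smooth.max() - smooth.min()
    scalar = lo + (smooth - smooth.min()) / (rng_span if rng_span > 0 else 1.0) * (hi - lo)

    hotspot_mask = _hotspot_region(size)
    background_mean = scalar[~hotspot_mask].mean()
    scalar[hotspot_mask] = hotspot_contrast * background_mean

    if noise_sd > 0:
        scalar = scalar + rng.normal(0.0, noise_sd, scalar.shape)
    scalar = np.clip(scalar, 0.0, 1.0)
    return Image(apply_colormap(scalar), Modality.PET), hotspot_mask, scalar


def make_pair(seed: int, config: PhantomConfig | None = None) -> PhantomPair:
    """Compose the structural and functional generators into one pair.

    Sub-seeds for the two generators are derived from ``seed`` through a
    seed sequence, so pairs with different seeds are independent and any
    single pair is bit-reproducible.
    """
    config = config or PhantomConfig()
    s_struct, s_func = (
        int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(2)
    )
    mri, edge_mask = make_structural(
        s_struct,
        size=config.size,
        n_ellipses=config.n_ellipses,
        edge_amp=config.edge_amp,
        noise_sd=config.structural_noise_sd,
    )
    pet, hotspot_mask, scalar = make_functional(
        mri,
        s_func,
        hotspot_contrast=config.hotspot_contrast,
        blur_sd=config.blur_sd,
        noise_sd=config.functional_noise_sd,
    )
    return PhantomPair(
        mri=mri,
        pet=pet,
        edge_mask=edge_mask,
        hotspot_mask=hotspot_mask,
        hotspot_contrast=config.hotspot_contrast,
        seed=seed,
        params=asdict(config) | {"sub_seeds": [s_struct, s_func]},
        functional_scalar=scalar,
    )
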