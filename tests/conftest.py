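import numpy as np
import pytest

from neurofuse import Image, Modality, PhantomConfig, make_pair

NOISE_FREE = PhantomConfig(structural_noise_sd=0.0, functional_noise_sd=0.0)


@pytest.fixture(scope="session")
def phantom_pair():
    """One noise-free 128x128 phantom pair, shared across tests."""
    return make_pair(0, NOISE_FREE)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_image(rng, size=32, channels=1, modality=Modality.OTHER) -> Image:
    return Image(rng.random((size, size, channels)), modality)


@pytest.fixture()
def gray32(rng):
    return random_image(rng, 32, 1)


@pytest.fixture()
def rgb32(rng):
    return random_image(rng, 32, 3)
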