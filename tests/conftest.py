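import numpy as np
import pytest

from histoseg import SyntheticParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Six easy 64x64 synthetic images with masks, shared across tests."""
    params = SyntheticParams(
        image_height=64,
        image_width=64,
        n_nuclei=4,
        radius_range=(8.0, 14.0),
        noise_sd=0.02,
        seed=99,
    )
    return generate_dataset(6, params)
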