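import numpy as np
import pytest

from salif.config import default_params
from salif.lif import NoiseParams
from salif.synthetic import generate_synthetic_saliency_map, random_map_set


@pytest.fixture(scope="session")
def bundle():
    """Shipped default (LIFParams, WTAParams, NoiseParams)."""
    return default_params()


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseParams(noise_ampl=0.0, noise_const=0.0, map_range=1e-9)


@pytest.fixture(scope="session")
def single_peak_map():
    return generate_synthetic_saliency_map(24, 32, [((10, 20), 0.8)], seed=3)


@pytest.fixture(scope="session")
def map_set():
    return random_map_set(10, shape=(16, 16), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
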