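import numpy as np
import pytest

from csag.synthetic import SyntheticParams, generate_lesion_sample


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_samples():
    """Three 64x64 synthetic pairs shared across tests."""
    params = SyntheticParams(image_size=64)
    return [generate_lesion_sample(params, seed) for seed in range(3)]
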