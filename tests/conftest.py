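import numpy as np
import pytest

from fluxprof.model import delete_reactions
from fluxprof.sampling import SamplerConfig
from fluxprof.synthetic import make_toy_fermentation_model


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_fermentation_model()


@pytest.fixture(scope="session")
def toy_nzn(toy_model):
    return delete_reactions(toy_model, ["LDH", "PFL"], new_id="toy_nzn")


@pytest.fixture
def quick_config():
    """Small sampler configuration for fast structural tests."""
    return SamplerConfig(n_samples=200, steps_per_sample=20, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
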