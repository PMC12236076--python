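import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    from phrfdet.model import ModelConfig

    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def small_scenes():
    """Six deterministic 160px scenes shared across tests."""
    from phrfdet.data import generate_dataset

    return generate_dataset(6, "multi", seed=11, image_size=160)
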