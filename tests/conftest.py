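import numpy as np
import pytest

from repi import ModelConfig, ParadigmConfig


@pytest.fixture
def simon_model():
    return ModelConfig.for_paradigm("simon")


@pytest.fixture
def switching_model():
    return ModelConfig.for_paradigm("switching")


@pytest.fixture
def small_paradigm():
    """A short trial sequence configuration for fast end-to-end tests."""
    return ParadigmConfig(n_trials=20, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
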