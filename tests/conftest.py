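import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from thzskin import FrequencyGrid, StackConfig
from thzskin.synthetic_data import make_reference_pulse


@pytest.fixture(scope="session")
def grid() -> FrequencyGrid:
    """A modest THz band grid covering the analysis band."""
    return FrequencyGrid(np.linspace(0.05, 2.0, 128))


@pytest.fixture(scope="session")
def stack_config() -> StackConfig:
    return StackConfig()


@pytest.fixture(scope="session")
def reference():
    return make_reference_pulse()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
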