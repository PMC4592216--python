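import numpy as np
import pytest

from hostswitch import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """Default configuration: the study's standard parameter set."""
    return SimulationParams()
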