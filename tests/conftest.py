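import numpy as np
import pytest

from culturesim import SimParams


@pytest.fixture
def default_params() -> SimParams:
    """The model's published default parameterisation."""
    return SimParams()


@pytest.fixture
def reduced_params() -> SimParams:
    """Reduced-horizon defaults for quicker equilibrium checks."""
    return SimParams().reduced()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
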