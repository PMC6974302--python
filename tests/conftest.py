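import numpy as np
import pytest

from chirosim.core import Params
from chirosim.state import SystemState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return Params()


def empty_state(params: Params, seed: int = 0) -> SystemState:
    """A state with the right geometry but no molecules (tests fill it)."""
    return SystemState(params, np.random.default_rng(seed))
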