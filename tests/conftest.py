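import numpy as np
import pytest

from swmsim import NetworkParams, RingGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fast network for mechanics tests (not the calibrated regime)."""
    return NetworkParams(n_neurons=60, j_peak=0.5, j_floor=-0.05)


@pytest.fixture
def default_params():
    """The calibrated defaults used by the experiments."""
    return NetworkParams()


@pytest.fixture
def small_grid():
    return RingGrid(60)
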