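import numpy as np
import pytest

from ratechaos.experiments import make_fixtures
from ratechaos.params import ModelParams
from ratechaos.topology import build_topology


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=7)


@pytest.fixture(scope="session")
def small_params():
    """A 40-neuron network, heavy enough to have both populations."""
    return ModelParams(N=40, C=10, f_E=0.8, J=0.5, g=5.0, delta=0.55, seed=11)


@pytest.fixture(scope="session")
def small_topology(small_params):
    return build_topology(small_params)


@pytest.fixture(scope="session")
def reduced_params():
    """Reduced-scale network used for dynamics tests: same connection
    probability and E/I architecture as the headline N=10000/C=1000 model."""
    return ModelParams(N=1000, C=100, f_E=0.8, J=0.5, g=5.0, delta=0.55, seed=5)


@pytest.fixture(scope="session")
def reduced_topology(reduced_params):
    return build_topology(reduced_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
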