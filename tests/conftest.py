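import numpy as np
import pytest

from lsasim import neural_core as nc
from lsasim.plasticity import STDPConfig


@pytest.fixture(scope="session")
def stdp_default():
    return STDPConfig()


@pytest.fixture()
def lsa3():
    return nc.build_minimal_circuit("lsa3", 2.0)


@pytest.fixture()
def two_neuron_net():
    """Strongly coupled pair with a 5 ms delay for timing-contract tests."""
    topo = nc.build_minimal_circuit("lsa2", 8.0, delay_ms=5.0)
    return topo


def poisson_train(rate_hz, duration_ms, rng):
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


@pytest.fixture()
def make_poisson_train():
    return poisson_train
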