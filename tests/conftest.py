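import numpy as np
import pytest

from ffinet.calibrate import Background
from ffinet.network import NetworkSpec, NeuronParams, build_connectivity
from ffinet.synth import fixture_network

# Shared operating conditions for network-level tests: the down-scaled
# (1600 E / 400 I) network preserving in-degree x weight of the default
# 8000/2000, 2%-sparsity model, with the standard background drive.
BG = Background(rate=15.0, weight=1.0)


@pytest.fixture(scope="session")
def fixture_spec():
    return fixture_network(0.2, NetworkSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_conn(fixture_spec):
    return build_connectivity(fixture_spec)


@pytest.fixture(scope="session")
def tiny_conn():
    """250-neuron network for fast simulator unit tests."""
    spec = NetworkSpec(n_e=200, n_i=50, sparsity=0.2, w_e=0.1, w_i=0.8,
                       seed=7)
    return build_connectivity(spec)


@pytest.fixture()
def single_neuron():
    """Two disconnected neurons (one E, one I); no synapses."""
    spec = NetworkSpec(n_e=1, n_i=1, sparsity=0.0, w_e=0.0, w_i=0.0,
                       seed=1)
    return build_connectivity(spec)


@pytest.fixture(scope="session")
def params():
    return NeuronParams()
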