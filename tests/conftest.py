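import numpy as np
import pytest

from tensionsnn.geometry import NetworkGeometry
from tensionsnn.params import NeuronParams, PlasticityParams, SynapseParams


def make_geometry(positions, inhibitory, lengths, synapses,
                  area=(1000.0, 1000.0), seed=0) -> NetworkGeometry:
    """Hand-built geometry for small deterministic tests."""
    syn = np.asarray(synapses, dtype=np.int32).reshape(-1, 2)
    if syn.size:
        order = np.lexsort((syn[:, 1], syn[:, 0]))
        syn = np.ascontiguousarray(syn[order])
    return NetworkGeometry(
        positions=np.asarray(positions, dtype=float),
        is_inhibitory=np.asarray(inhibitory, dtype=bool),
        neurite_length=np.asarray(lengths, dtype=float),
        synapses=syn, area=area, seed=seed)


@pytest.fixture
def neuron_params():
    return NeuronParams()


@pytest.fixture
def synapse_params():
    return SynapseParams()


@pytest.fixture
def plasticity_params():
    return PlasticityParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
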