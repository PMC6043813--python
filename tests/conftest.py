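import numpy as np
import pytest

from topoplast.topology import GridLayer
from topoplast.neurons import NeuronParams
from topoplast.synapses import STDPParams
from topoplast.rewiring import RewiringParams
from topoplast.stimulus import StimulusParams
from topoplast.init_connectivity import InitSpec, generate_topographic


@pytest.fixture(scope="session")
def grid16():
    return GridLayer(16, 16)


@pytest.fixture(scope="session")
def grid8():
    return GridLayer(8, 8)


@pytest.fixture(scope="session")
def neuron_params():
    return NeuronParams()


@pytest.fixture(scope="session")
def stdp_params():
    return STDPParams()


@pytest.fixture(scope="session")
def rewiring_params():
    return RewiringParams()


@pytest.fixture(scope="session")
def stimulus_params():
    return StimulusParams()


@pytest.fixture(scope="session")
def topographic_map(grid16, rewiring_params):
    """The standard rough topographic map (16 ff + 16 lat afferents)."""
    rng = np.random.default_rng(2024)
    return generate_topographic(grid16, InitSpec(), rewiring_params, rng)
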