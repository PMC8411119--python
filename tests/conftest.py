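import numpy as np
import pytest

from idipnet.core import (NeuronParams, NeuronPopulation, SynapseParams,
                          SynapticProjection)


@pytest.fixture
def lif_pop():
    """Single default LIF neuron (table parameters)."""
    return NeuronPopulation(1, NeuronParams(), "p")


@pytest.fixture
def two_pop_projection():
    """2-pre -> 3-post excitatory projection with unit coupling."""
    pre = NeuronPopulation(2, NeuronParams(), "pre")
    post = NeuronPopulation(3, NeuronParams(), "post")
    W = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 0.5]])
    mask = W > 0
    proj = SynapticProjection(pre, post, W,
                              SynapseParams(g_bar=1.0, v_rev=0.0, tau=5.0,
                                            coupling=1.0), mask, "t")
    return pre, post, proj
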