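import numpy as np
import pytest

from axonet.channels import channel_registry
from axonet.presets import final_network, passive_network


@pytest.fixture(scope="session")
def registry():
    return channel_registry()


@pytest.fixture(scope="session")
def final_model():
    """One fixed realisation of the final active coupled network."""
    return final_network(3)


@pytest.fixture(scope="session")
def final_uncoupled(final_model):
    return final_model.uncoupled()


@pytest.fixture(scope="session")
def passive_coupled():
    """A passive coupled column at the uniform leak density."""
    model, system = passive_network(7, g_lk=0.25)
    return model, system


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
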