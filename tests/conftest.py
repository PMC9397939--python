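import numpy as np
import pytest

from epispread.model_core import EpileptorParams
from epispread.synthetic import SynthSpec, synth_connectome, synth_fixtures


@pytest.fixture(scope="session")
def params():
    return EpileptorParams()


@pytest.fixture(scope="session")
def two_node():
    return synth_fixtures("two_node")


@pytest.fixture(scope="session")
def chain4():
    return synth_fixtures("chain", 4)


@pytest.fixture(scope="session")
def star8():
    return synth_fixtures("star_hub", 8)


@pytest.fixture(scope="session")
def net3():
    return synth_connectome(SynthSpec(n_nodes=3, density=1.0, seed=2))


@pytest.fixture(scope="session")
def net10():
    """The 10-node heavy-tailed synthetic network used throughout."""
    return synth_connectome(SynthSpec(n_nodes=10, density=0.5, seed=0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
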