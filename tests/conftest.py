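import numpy as np
import pytest

from frustfold import ModelParams, build_topology
from frustfold.fixtures import make_hairpin, make_mock_sandwich, make_toy_chain


@pytest.fixture(scope="session")
def hairpin_topology():
    return build_topology(make_hairpin(12, seed=0))


@pytest.fixture(scope="session")
def sandwich():
    structure, ss = make_mock_sandwich(seed=0)
    return structure, build_topology(structure, ss_elements=ss)


@pytest.fixture(scope="session")
def toy_topology():
    return build_topology(make_toy_chain(10, seed=1))


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
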