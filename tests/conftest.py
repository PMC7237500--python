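import numpy as np
import pytest

from fomotor.structure_io import build_ideal_fixture
from fomotor.topology_energy import make_topology


@pytest.fixture(scope="session")
def fixture_structure():
    return build_ideal_fixture()


@pytest.fixture(scope="session")
def fixture_topology(fixture_structure):
    return make_topology(fixture_structure)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
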