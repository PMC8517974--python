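import numpy as np
import pytest

from znmt.colvars import cn_znS_defaults
from znmt.synthetic import make_star_topology
from znmt.topology import default_sequence, mt2_default_topology


@pytest.fixture(scope="session")
def sequence():
    return default_sequence()


@pytest.fixture(scope="session")
def mt2_topology():
    """Full Zn7 two-cluster topology (bridged graphs)."""
    return mt2_default_topology()


@pytest.fixture(scope="session")
def star_topology():
    """Dedicated-ligand 5-metal topology used by the trajectory generator."""
    return make_star_topology()


@pytest.fixture(scope="session")
def znS_params():
    return cn_znS_defaults()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
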