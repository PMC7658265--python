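import numpy as np
import pytest

from turingcells.model import ArrayTopology, KineticParams, build_topology


@pytest.fixture(scope="session")
def gate_params():
    """The standard chemical-computing operating point."""
    return KineticParams()  # sigma_M=100, sigma_inh=35, k_ADP=0.1, q=1


@pytest.fixture(scope="session")
def single_cell():
    return ArrayTopology(N=1, delta=np.zeros((1, 1)))


@pytest.fixture(scope="session")
def two_cell():
    return build_topology("linear", 2)


@pytest.fixture(scope="session")
def cyclic3():
    return build_topology("cyclic", 3)


@pytest.fixture(scope="session")
def random_fixtures():
    """Seeded random topologies/parameters with known-by-construction facts."""
    from turingcells.workbench import generate_fixtures

    return generate_fixtures(seed=20, n_fixtures=6)
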