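import numpy as np
import pytest

from tactilesnn import build_population
from tactilesnn.cuneate import build_cn
from tactilesnn.cortex import build_cortical_rfs
from tactilesnn.grid import MechanoreceptorGrid


@pytest.fixture(scope="session")
def grid():
    return MechanoreceptorGrid()


@pytest.fixture(scope="session")
def sa_pop(grid):
    return build_population("SA", grid, rng=11)


@pytest.fixture(scope="session")
def ra_pop(grid):
    return build_population("RA", grid, rng=12)


@pytest.fixture(scope="session")
def cn_net(sa_pop, ra_pop):
    return build_cn(sa_pop, ra_pop, inhibition_level=1.0, rng=2)


@pytest.fixture(scope="session")
def cortex_net(cn_net):
    return build_cortical_rfs(cn_net)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
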