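import numpy as np
import pytest

from samdyn import MeristemModel, Parameters
from samdyn.grid import RadialGrid


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def fitted():
    """Calibrated wild-type equilibrium (packaged fixture)."""
    return MeristemModel.from_fixture()


@pytest.fixture(scope="session")
def grid():
    return RadialGrid(200)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
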