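import numpy as np
import pytest

from nanopose.energy import InfinitePlane, SystemSpec
from nanopose.fixtures import MockSpec, make_mock_doxh
from nanopose.forcefield import default_forcefield
from nanopose.structures import Atom, RigidMolecule


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def cc_pair(ff):
    return ff.pair("C", "C")


@pytest.fixture(scope="session")
def mock_mol():
    return make_mock_doxh(MockSpec(seed=0))


@pytest.fixture(scope="session")
def single_carbon():
    """One-atom probe 'molecule' (no ring anchors)."""
    return RigidMolecule([Atom("C1", "C", (0.0, 0.0, 0.0))], plane_anchors=None)


@pytest.fixture(scope="session")
def plane_system(single_carbon, ff):
    return SystemSpec((single_carbon,), plane=InfinitePlane(), forcefield=ff)


@pytest.fixture(scope="session")
def dimer_system(single_carbon, ff):
    return SystemSpec((single_carbon, single_carbon), plane=None, forcefield=ff)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
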