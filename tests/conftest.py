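import numpy as np
import pytest

from oligovar.energetics import EnergyModel
from oligovar.mutagenesis import MutationSpec
from oligovar.synthetic import FixtureSpec, make_c3_trimer, make_point_charge_cluster


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def c3_trimer(fixture_spec):
    """Exact-C3 trimer with the planted interface glutamine (do not mutate in place)."""
    trimer, meta = make_c3_trimer(fixture_spec)
    return trimer, meta


@pytest.fixture(scope="session")
def qe_spec():
    return MutationSpec("A", 180, "Q", "E")


@pytest.fixture(scope="session")
def mm_model():
    return EnergyModel()


@pytest.fixture(scope="session")
def toy_model():
    return EnergyModel.toy()


@pytest.fixture()
def dipole_cluster():
    return make_point_charge_cluster([1.0, -1.0], [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
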