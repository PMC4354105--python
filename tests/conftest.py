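import warnings

import pytest

from thermoefm import (chain_model, diamond_model, gen_thermo_fixture,
                       reversible_pair_model, split_reversible)
from thermoefm.thermo import MetaboliteThermo, ThermoData

warnings.filterwarnings("ignore", message=".*thermo entries match no model.*")


@pytest.fixture(scope="session")
def chain():
    """->M0 -> M1 -> M2 -> M3 -> out: a 5-reaction linear chain, one EFM."""
    return chain_model(3)


@pytest.fixture(scope="session")
def chain3():
    """->M0 -> M1 -> out: the minimal 3-reaction chain."""
    return chain_model(1)


@pytest.fixture(scope="session")
def diamond():
    return diamond_model()


@pytest.fixture(scope="session")
def rev_pair():
    return reversible_pair_model()


@pytest.fixture(scope="session")
def rev_pair_split(rev_pair):
    return split_reversible(rev_pair)


@pytest.fixture(scope="session")
def motif_thermo(chain):
    """Thermo fixture planting the interior reaction triple of the chain
    infeasible while every proper subset stays feasible (the
    glycolysis/gluconeogenesis-style motif)."""
    return gen_thermo_fixture(chain, planted_infeasible=[frozenset({1, 2, 3})],
                              seed=1)


@pytest.fixture()
def simple_thermo():
    """Two metabolites with fixed energies, wide-ish concentration ranges."""
    return ThermoData({
        "M0": MetaboliteThermo(0.0, 1e-3, 1e-1),
        "M1": MetaboliteThermo(0.0, 1e-3, 1e-1),
    })


def write_tsv(path, text):
    path.write_text(text)
    return path
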