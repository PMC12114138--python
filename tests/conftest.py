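import pytest

from oglyco.digest import FSH_CTP, Glycopeptide, PeptideSpan, enumerate_glycopeptides
from oglyco.glycans import CORE1
from oglyco.simulate import CTP_GLYCOSITES, fsh_ctp_inventory


@pytest.fixture(scope="session")
def ctp():
    return FSH_CTP


@pytest.fixture(scope="session")
def core1():
    return CORE1


@pytest.fixture(scope="session")
def inventory():
    """The sixteen observed (glycopeptide, charge) pairs."""
    return fsh_ctp_inventory()


@pytest.fixture(scope="session")
def candidate_space():
    """Closed search space over the seven-candidate glycosite set."""
    return enumerate_glycopeptides(
        FSH_CTP, CTP_GLYCOSITES, [CORE1], max_missed=3,
        mode="specific", occupancy="partial",
    )


def make_glycopeptide(sequence, start, sites, glycan=CORE1):
    span = PeptideSpan(sequence, start, start + len(sequence) - 1)
    return Glycopeptide(span, {s: glycan for s in sites})


@pytest.fixture(scope="session")
def gp_factory():
    return make_glycopeptide
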