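import pytest
from hypothesis import settings

from siftkit import synthetic as syn
from siftkit.fingerprint import GeometricCriteria

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

ALL_KINDS = ("hbond_donor", "hbond_acceptor", "hydrophobic", "polar",
             "charged", "aromatic", "contact", "backbone")


@pytest.fixture(scope="session")
def criteria():
    return GeometricCriteria()


@pytest.fixture(scope="session")
def planted_all():
    """One pocket complex with one planted interaction of every class."""
    return syn.make_planted_complex(syn.PlantSpec(
        interactions=[syn.planted_interaction(k) for k in ALL_KINDS]))


@pytest.fixture(scope="session")
def planted_trio():
    """Smaller pocket with three planted interactions (fast ensemble base)."""
    return syn.make_planted_complex(syn.PlantSpec(interactions=[
        syn.planted_interaction("hbond_donor"),
        syn.planted_interaction("hydrophobic"),
        syn.planted_interaction("charged"),
    ]))


@pytest.fixture(scope="session")
def catalytic_complex():
    return syn.make_catalytic_site_complex()
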