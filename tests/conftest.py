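import pytest
from hypothesis import HealthCheck, settings

from pbscreen.zinc_finger import RecognitionCode
from pbscreen import synthetic_data as syn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Finger 1 of Zif268 with flanking residues; recognition helix RSDELTR,
#: the textbook anchor for fingerprint extraction (R, D, E, R -> GCG).
ZIF268_FINGER1 = "PYACPVESCDRRFSRSDELTRHIRIHTG"


@pytest.fixture(scope="session")
def catalog():
    return syn.default_catalog()


@pytest.fixture(scope="session")
def pro_motif(catalog):
    return next(m for m in catalog if m.trna_id == "Pro")


@pytest.fixture(scope="session")
def code():
    return RecognitionCode.complete()


@pytest.fixture(scope="session")
def standins():
    return syn.standin_reference_proteins()


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study shared by read-only tests."""
    return syn.simulate_all(1)
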