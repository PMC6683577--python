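import pytest

from robaudit import build_taxonomy, default_ruleset
from robaudit.ingest import RoBEntry

SEQ_DOMAIN = "Random sequence generation (selection bias)"


@pytest.fixture(scope="session")
def taxonomy():
    return build_taxonomy()


@pytest.fixture(scope="session")
def strict_taxonomy():
    return build_taxonomy(strict_handbook=True)


@pytest.fixture(scope="session")
def rules():
    return default_ruleset()


def make_entry(
    review="R1",
    study="S1",
    domain=SEQ_DOMAIN,
    judgment="Low risk",
    support="Computer generated randomisation list.",
    design=None,
):
    return RoBEntry.from_fields(review, study, domain, judgment, support, design)


@pytest.fixture
def entry_factory():
    return make_entry
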