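import pytest
from hypothesis import settings

from woodwhite import fixtures

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coi_table():
    return fixtures.coi_site_table()


@pytest.fixture(scope="session")
def coi_alleles():
    return fixtures.coi_allele_alignment()


@pytest.fixture(scope="session")
def morpho_records():
    return fixtures.morpho_records()


@pytest.fixture(scope="session")
def enzymes():
    return {e.name: e for e in fixtures.default_enzyme_library()}
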