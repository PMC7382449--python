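import pytest
from hypothesis import settings

from triovar import fixtures

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pedigrees():
    return fixtures.load_pedigrees()


@pytest.fixture(scope="session")
def table3_rows(pedigrees):
    return fixtures.load_table3(pedigrees)


@pytest.fixture(scope="session")
def fixture_pipeline_inputs():
    """(GenotypeTable, annotations, pedigrees) for the packaged cohort."""
    return fixtures.table3_genotype_table()


@pytest.fixture(scope="session")
def brain_profiles():
    return fixtures.load_brain_expression()


@pytest.fixture(scope="session")
def table2_frame():
    return fixtures.load_table2()
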