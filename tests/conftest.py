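import pytest

from lofburden import datasets, filter_deleterious
from lofburden.simulate import default_transcript_model


@pytest.fixture(scope="session")
def model():
    """Bundled transcript/domain model (no CDS sequence attached)."""
    return datasets.load_transcript_model()


@pytest.fixture(scope="session")
def seq_model():
    """Synthetic transcript with a CDS sequence for translation tests."""
    return default_transcript_model()


@pytest.fixture(scope="session")
def variants(model):
    return datasets.load_variants(model)


@pytest.fixture(scope="session")
def lof_variants(variants):
    return [v for v in filter_deleterious(variants) if v.is_lof]


@pytest.fixture(scope="session")
def cohorts():
    return datasets.load_cohorts()


@pytest.fixture(scope="session")
def strata(cohorts):
    return cohorts[0]


@pytest.fixture(scope="session")
def cohort_sets(cohorts):
    return cohorts[1]


@pytest.fixture(scope="session")
def references():
    return datasets.load_references()
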