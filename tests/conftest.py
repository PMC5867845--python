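import pytest

from mthet import MtReference, classify_dataset, fixtures_from_tables


@pytest.fixture(scope="session")
def reference():
    return MtReference.load()


@pytest.fixture(scope="session")
def cohort(reference):
    """The 39-family cohort reconstructed from the packaged tables."""
    return fixtures_from_tables(reference)


@pytest.fixture(scope="session")
def classified(reference, cohort):
    """Full calling + classification of the fixture cohort."""
    return classify_dataset(cohort.pileup, cohort.manifest, reference=reference)
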