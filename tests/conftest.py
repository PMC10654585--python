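import pytest

from hostswitch.datasets import (
    molothrus_lineage_tanglegrams,
    reference_evidence,
    reference_occurrence_dataset,
)


@pytest.fixture(scope="session")
def reference_dataset():
    """The published 144-host / 365-record occurrence survey."""
    return reference_occurrence_dataset()


@pytest.fixture(scope="session")
def evidence():
    return reference_evidence()


@pytest.fixture(scope="session")
def lineage_tanglegrams():
    return molothrus_lineage_tanglegrams()
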