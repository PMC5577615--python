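import pytest

from mytimine import load_reference_peptides

FUNCTIONAL_IDS = ("A3", "A4", "A5", "C10")


@pytest.fixture(scope="session")
def reference():
    """Packaged reference peptides keyed by id."""
    return {rec.id: rec for rec in load_reference_peptides()}


@pytest.fixture(scope="session")
def functional(reference):
    """The four functional mature peptides (amidation per the record)."""
    return [reference[i] for i in FUNCTIONAL_IDS]
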