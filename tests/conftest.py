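import pytest

from platmark.signatures import load_signature_reference
from platmark.synthetic_data import build_reference_fixture


@pytest.fixture(scope="session")
def fixture_cohort_matrix():
    """The frozen 16-patient reference cohort and its marker matrix."""
    return build_reference_fixture()


@pytest.fixture(scope="session")
def sig_ref():
    """The packaged synthetic 30-signature reference."""
    return load_signature_reference()
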