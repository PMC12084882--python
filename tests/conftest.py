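import pytest
from hypothesis import settings

from riboaudit.alignment import AlignmentParams
from riboaudit.synthetic import make_reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def ref_300():
    return make_reference(300, seed=42, record_id="ref300")


@pytest.fixture(scope="session")
def ref_1869():
    """A reference at the 18S template length, for fixture realism."""
    return make_reference(1869, seed=7, record_id="ref18S")
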