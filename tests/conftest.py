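import pytest
from hypothesis import settings

from haplopipe import build_study_fixture, motif

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def study():
    """Fresh study fixture per test (tests mutate sample records)."""
    return build_study_fixture()


@pytest.fixture
def s1():
    return motif([16298, 16327])


@pytest.fixture
def s2():
    return motif([16223, 16298, 16309, 16327])


@pytest.fixture
def ancestral():
    return motif([16223, 16298, 16327])
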