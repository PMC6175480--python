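import pytest
from hypothesis import settings

from uorfkit import build_fixture
from uorfkit.synthetic import FixtureSpec

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_model():
    """The TWIST1-like fixture transcript (L=300 leader, 51 nt CDS)."""
    return build_fixture(FixtureSpec())
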