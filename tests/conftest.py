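import pytest

from cbedesign.fixtures import FixtureSpec, synth_genome
from cbedesign.target_scan import ScanParams


@pytest.fixture(scope="session")
def default_params():
    return ScanParams()


@pytest.fixture(scope="session")
def fixture_genome():
    """Shared synthetic genome (seed 1) with its genes and truth table."""
    return synth_genome(FixtureSpec(seed=1))
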