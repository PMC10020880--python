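import pytest

from lunginterval import SyntheticConfig, generate_cohort, table1_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The exact 10,831-screen expansion of the published Lung-RADS counts."""
    return table1_fixture()


@pytest.fixture(scope="session")
def big_cohort():
    """Default-condition synthetic cohort at n=100,000 (shared; generation is
    the expensive step)."""
    return generate_cohort(SyntheticConfig(n_screens=100_000, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """Default-condition synthetic cohort at n=20,000 for model-fitting tests."""
    return generate_cohort(SyntheticConfig(n_screens=20_000, seed=11))
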