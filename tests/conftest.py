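import pytest

from kgemr import (CohortConfig, FixtureSpec, generate_cohort,
                   generate_kg_fixture)


@pytest.fixture(scope="session")
def fixture():
    """Default knowledge fixture (worked examples + 5 signal / 30 noise)."""
    return generate_kg_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort(fixture):
    """A 60-patient balanced cohort for fast pipeline tests."""
    config = CohortConfig(n_hospitalized=30, n_not_hospitalized=30, seed=1)
    records, truth = generate_cohort(config, fixture)
    return records, truth
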