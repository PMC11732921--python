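import pytest

from substature import (
    SimulationConfig,
    fit_all,
    load_registry,
    simulate_cohort,
    train_test_split,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def cohort():
    """Default-size synthetic cohort shared across modules."""
    return simulate_cohort(SimulationConfig(n=1000, seed=42))


@pytest.fixture(scope="session")
def split(cohort):
    return train_test_split(cohort, 0.8, seed=42)


@pytest.fixture(scope="session")
def fitted(split):
    train, _ = split
    return fit_all(train)
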