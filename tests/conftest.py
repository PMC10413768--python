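import pytest

from reekit.anthro import synthetic_lms_table
from reekit.equations import equation_registry
from reekit.synth import GeneratorConfig, assign_groups, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return equation_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=275, seed 1) with BMI groups assigned."""
    return assign_groups(simulate_cohort(GeneratorConfig(seed=1)))


@pytest.fixture(scope="session")
def large_cohort():
    """Large-n smoke cohort for moment-recovery checks."""
    return simulate_cohort(GeneratorConfig(seed=7, n=100_000))


@pytest.fixture(scope="session")
def lms_table():
    return synthetic_lms_table()
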