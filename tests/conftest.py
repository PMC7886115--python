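import pytest
from hypothesis import HealthCheck, settings

from xorseq import (
    customer_count_design,
    customer_profile_design,
    menu_design,
    reshape_long,
    simulate_cohort,
    switched_xor_design,
    xor_design,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def xor():
    return xor_design()


@pytest.fixture(scope="session")
def switched():
    return switched_xor_design()


@pytest.fixture(scope="session")
def menus():
    return menu_design()


@pytest.fixture(scope="session")
def customers():
    return customer_count_design()


@pytest.fixture(scope="session")
def profiles():
    return customer_profile_design()


@pytest.fixture(scope="session")
def small_cohort(xor):
    """A 6-participant, 4-block cohort with default learner parameters."""
    return simulate_cohort(xor, n_participants=6, master_seed=42, n_blocks=4)


@pytest.fixture(scope="session")
def small_long(small_cohort, xor):
    return reshape_long(small_cohort, xor)
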