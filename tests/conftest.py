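import pytest
from hypothesis import HealthCheck, settings

from cpbsim.impact import builtin_menu_path, read_service_menu
from cpbsim.literature import load_rate_table
from cpbsim.synth import make_influenza_like

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def influenza():
    """(model, ranges) for the shipped influenza-like cohort model."""
    return make_influenza_like()


@pytest.fixture(scope="session")
def rate_table():
    """Published QALY-rate table (printed SDs)."""
    return load_rate_table()


@pytest.fixture(scope="session")
def current_menu(rate_table):
    return read_service_menu(builtin_menu_path("ucc_current"), rate_table)


@pytest.fixture(scope="session")
def prospective_menu(rate_table):
    return read_service_menu(builtin_menu_path("ucc_prospective"), rate_table)
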