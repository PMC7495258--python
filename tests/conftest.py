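import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_registry():
    from pumplink.synthetic import CohortConfig, _build_registry

    return _build_registry(CohortConfig(n_patients=50))


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-size cohort under the default (study-shaped) error
    mixture, shared across read-only tests."""
    from pumplink import CohortConfig, ErrorMixture, generate_cohort

    return generate_cohort(CohortConfig(n_patients=40, seed=7), ErrorMixture())


@pytest.fixture(scope="session")
def default_bundle(default_cohort):
    from pumplink import run_streams

    c = default_cohort
    return run_streams(c.orders, c.order_events, c.mars, c.sprs, c.registry, c.drug_library)
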