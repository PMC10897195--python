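import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-variant seeded cohort shared by recovery tests."""
    from bescope.synthetic_data import generate_cohort

    return generate_cohort(400, seed=11)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    from bescope.pipeline import analyze_cohort

    return analyze_cohort(small_cohort)
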