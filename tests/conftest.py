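import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_fixture_sites():
    """Packaged two-day three-site synthetic experiment, noiseless regime."""
    from perchtrap.pipeline import make_fixtures

    return make_fixtures(seed=0, noiseless=True)
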