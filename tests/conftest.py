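import pytest
from hypothesis import HealthCheck, settings

from rtcea import study_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_config():
    """The built-in two-arm study configuration (session-cached)."""
    return study_fixture()
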