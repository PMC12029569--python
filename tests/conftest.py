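import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from g4probe.sequences import as1411_family  # noqa: E402


@pytest.fixture(scope="session")
def family():
    """AS1411 derivative family keyed by id."""
    return {s.id: s for s in as1411_family()}
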