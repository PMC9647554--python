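import pytest
from hypothesis import HealthCheck, settings

from insomnia_cea import reference_parameters

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """The reference parameter set (session-wide; it is immutable)."""
    return reference_parameters()
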