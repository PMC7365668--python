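import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from drgpop.protocol import make_protocol  # noqa: E402


@pytest.fixture(scope="session")
def pressure_protocol():
    return make_protocol("pressure_ramp", sampling_rate=4.0, baseline_duration_s=20.0)


@pytest.fixture(scope="session")
def movement_protocol():
    return make_protocol("movement", sampling_rate=4.0, baseline_duration_s=20.0)
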