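import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ylineage.simulate import make_fixture


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def table1_like():
    return make_fixture("table1-like")


@pytest.fixture(scope="session")
def qr_network():
    return make_fixture("qr-network")
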