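import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def xpd():
    from translokit.synthetic import build_xpd_fixture
    return build_xpd_fixture()


@pytest.fixture(scope="session")
def ding():
    from translokit.synthetic import build_ding_fixture
    return build_ding_fixture()


@pytest.fixture(scope="session")
def xpd_topology(xpd):
    return xpd[0]


@pytest.fixture(scope="session")
def xpd_fixture(xpd):
    return xpd[1]


@pytest.fixture(scope="session")
def ding_fixture(ding):
    return ding[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
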