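import pytest
from hypothesis import HealthCheck, settings

from cogbattery import default_battery

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def en_battery():
    return default_battery("en")


@pytest.fixture(scope="session")
def da_battery():
    return default_battery("da")
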