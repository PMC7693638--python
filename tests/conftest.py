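import pytest
from hypothesis import HealthCheck, settings

from mpsflow import presets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def water():
    return presets.WATER


@pytest.fixture
def membrane():
    return presets.MEMBRANE


@pytest.fixture
def apical():
    return presets.APICAL_CHANNEL


@pytest.fixture
def basal():
    return presets.BASAL_CHANNEL


@pytest.fixture
def planform():
    return presets.PLANFORM
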