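import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from txlogic.synthetic_data import NoiseModel


@pytest.fixture
def default_noise() -> NoiseModel:
    return NoiseModel()


@pytest.fixture
def zero_noise() -> NoiseModel:
    return NoiseModel(cv_fluorescence=0.0, cv_od=0.0)
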