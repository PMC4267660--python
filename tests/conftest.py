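import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def calibration_model():
    from rnafret.calibration import CalibrationModel

    return CalibrationModel(r_eff=8.5, sigma_r_eff=0.0)
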