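import pytest
from hypothesis import HealthCheck, settings

from spakit.simulate import SimulationConfig, scenario_preset

settings.register_profile(
    "spakit",
    max_examples=60,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("spakit")


@pytest.fixture
def ideal_config() -> SimulationConfig:
    """Pure-diffusion limit: constant volume, no residual fluid, no noise.

    On this configuration the Garred estimator's model assumptions hold
    exactly, so parameter recovery must be exact to floating precision.
    """
    return SimulationConfig(
        residual_volume_true=0.0,
        uf_rate_initial=0.0,
        lymphatic_rate=0.0,
        sample_retained_volume=0.0,
        noise_cv=0.0,
    )


@pytest.fixture
def quiet_low_transporter() -> SimulationConfig:
    """The low-transport study conditions with measurement noise switched off."""
    return scenario_preset("low_transporter", noise_cv=0.0)
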