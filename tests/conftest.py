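import pytest
from hypothesis import HealthCheck, settings

from clleach.synth import GeneratorConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Sampling grid with dense early coverage, as a leaching trial chasing
#: low-rain efficiency would schedule it.
MILESTONE_RAIN = (20.0, 45.0, 70.0, 100.0, 130.0, 170.0, 210.0, 250.0, 300.0)


@pytest.fixture(scope="session")
def loam_trial():
    from clleach.synth import generate_trial

    return generate_trial(GeneratorConfig(seed=7))


@pytest.fixture
def milestone_config():
    return GeneratorConfig(seed=7, sampling_rain=MILESTONE_RAIN)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(seed=7, sampling_rain=MILESTONE_RAIN, noise_sd=0.0)
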