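import pytest
from hypothesis import HealthCheck, settings

from shrimpdeb import DEBParams, ScenarioSpec, gen_growth_observations, gen_temperature

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> DEBParams:
    return DEBParams.default()


@pytest.fixture(scope="session")
def pond_spec_noiseless() -> ScenarioSpec:
    """Pond scenario with the deterministic temperature cycle and no
    observation noise: the round-trip ground truth."""
    return ScenarioSpec(obs_cv=0.0, temp_noise_sd_C=0.0)


@pytest.fixture(scope="session")
def noiseless_pond(params, pond_spec_noiseless):
    """(observations, forcing) for the noiseless pond scenario."""
    obs = gen_growth_observations(pond_spec_noiseless, params)
    forcing = gen_temperature(pond_spec_noiseless)
    return obs, forcing
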