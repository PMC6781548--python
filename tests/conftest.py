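import pytest
from hypothesis import HealthCheck, settings

from pegsax.core import default_parameters
from pegsax.synth import OBSERVED_SPECIES, StudyDesign, generate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth_params():
    return default_parameters()


@pytest.fixture(scope="session")
def noiseless_study(truth_params):
    """Full factorial design, no noise, default censoring."""
    return generate_study(StudyDesign(noise_sigma=0.0), truth_params)


@pytest.fixture(scope="session")
def noiseless_uncensored_study(truth_params):
    """Full factorial design, no noise, no quantitation limits."""
    design = StudyDesign(
        noise_sigma=0.0, loq_ppm={sp: 0.0 for sp in OBSERVED_SPECIES}
    )
    return generate_study(design, truth_params)


@pytest.fixture(scope="session")
def small_design():
    """Reduced design for regression tests that refit parameters."""
    return StudyDesign(
        peg_saxa_ratios=(0.8, 1.4),
        temperatures_c=(40.0, 50.0),
        water_activities=(0.10, 0.30),
        time_days=(0.0, 14.0, 60.0, 120.0, 180.0),
        noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def small_study(small_design, truth_params):
    return generate_study(small_design, truth_params)
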