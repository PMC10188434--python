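import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

from chla3d.synthetic import SamplingSpec, TruthFieldSpec, sample_stations, truth_grid

SCENARIO_SEED = 7


@pytest.fixture(scope="session")
def truth_spec():
    return TruthFieldSpec()


@pytest.fixture(scope="session")
def paperlike_stations(truth_spec):
    """Default noisy survey: 368/99/13 stations, sigma = 0.1."""
    return sample_stations(truth_spec, SamplingSpec(), seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def noiseless_stations(truth_spec):
    return sample_stations(truth_spec, SamplingSpec(noise_sigma_log10=0.0),
                           seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def truth_field(truth_spec):
    return truth_grid(truth_spec, resolution_deg=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
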