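import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import reefdiss as rd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_samples():
    """Seeded synthetic dissolution-experiment table under the default design."""
    return rd.simulate_dissolution_experiment(rd.ExperimentDesign(seed=0))


@pytest.fixture(scope="session")
def default_analysis(default_samples):
    return rd.DissolutionExperiment(default_samples).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
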