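import numpy as np
import pytest

from thermaldev import AnalysisConfig, DevelopmentStudy
from thermaldev.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    """Reference study design: 11 temperatures, 20 eggs, 4 replicates."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_report(default_cohort):
    return DevelopmentStudy(default_cohort, AnalysisConfig()).run()


@pytest.fixture(scope="session")
def noiseless_config():
    """cv = 0, no curvature, dense schedule: each transition is a step
    function localised only to its sampling interval, so a fine grid is used
    for quantisation-limited ground-truth recovery."""
    temps = tuple(np.round(np.arange(15.0, 32.51, 2.5), 1))
    return SimulationConfig(
        temperatures=temps,
        transition_cv=0.0,
        curvature_strength=0.0,
        eggs_per_cup=1,
        replicates=1,
        samples_per_stage=60,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_report(noiseless_config):
    obs = generate_cohort(noiseless_config)
    return DevelopmentStudy(obs, AnalysisConfig()).run()
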