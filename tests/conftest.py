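import numpy as np
import pytest

from moodsim import SimulationConfig, build_agent_model, run_study
from moodsim.environment import SocialEnvironment

N_SEEDS = 20
MASTER_SEED = 11


@pytest.fixture
def model():
    """Fresh default agent model for the social task."""
    return build_agent_model()


@pytest.fixture
def env():
    return SocialEnvironment(rng_seed=123)


@pytest.fixture(scope="session")
def config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def study(config):
    """The full nine-condition study at the default study conditions.

    Shared across acceptance tests; 20 seeds per condition.
    """
    return run_study(config, condition_ids=list(range(9)), n_seeds=N_SEEDS,
                     master_seed=MASTER_SEED)
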