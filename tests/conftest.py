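import numpy as np
import pytest

from acticut.cohort import SimulationConfig, simulate_cohort
from acticut.pipeline import build_study_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def cohort_dataset():
    """One simulated 20-participant study and its long observation table."""
    cfg = SimulationConfig(seed=7)
    sessions = simulate_cohort(cfg)
    return sessions, build_study_dataset(sessions)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
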