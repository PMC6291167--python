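import warnings

import numpy as np
import pytest

from pupilrl.qlearning import AgentParams
from pupilrl.task import EventTiming, PairSpec, TaskConfig

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()

@pytest.fixture()
def small_config() -> TaskConfig:
    """Short two-pair session for cheap tests."""
    return TaskConfig(
        pairs=[PairSpec("A", "B", 0.8), PairSpec("C", "D", 0.7)],
        n_runs_learning=2,
        trials_per_run=30,
        n_runs_transfer=1,
        transfer_pairs=[("A", "B"), ("C", "D"), ("A", "C")],
    )


@pytest.fixture()
def tiny_learning_config() -> TaskConfig:
    return TaskConfig(
        pairs=[PairSpec("A", "B", 0.8)],
        n_runs_learning=1,
        trials_per_run=10,
        n_runs_transfer=0,
    )


@pytest.fixture()
def agent_params() -> AgentParams:
    return AgentParams(alpha_gain=0.4, alpha_loss=0.2, beta=6.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
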