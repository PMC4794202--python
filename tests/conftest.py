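import numpy as np
import pytest

from twostep.agent import ParameterSet, SessionData, simulate_session
from twostep.task import TaskConfig, build_reward_schedule


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def short_config() -> TaskConfig:
    return TaskConfig(n_trials=30, break_after=(10, 20))


@pytest.fixture(scope="session")
def mid_params() -> ParameterSet:
    """Well-identified parameter values in the interior of the space."""
    return ParameterSet(alpha1=0.6, alpha2=0.7, lam=0.6, beta2=4.0,
                        beta_hb=2.0, beta_gd=4.0, p=0.3)


@pytest.fixture
def short_session(short_config, mid_params) -> SessionData:
    schedule = build_reward_schedule(short_config, seed=7)
    return simulate_session(mid_params, short_config, schedule, seed=8)


def random_session(n_trials: int, seed: int) -> SessionData:
    """A session of arbitrary (not model-generated) trial outcomes."""
    rng = np.random.default_rng(seed)
    return SessionData(
        subject_id=f"r{seed}", condition="na",
        choice1=rng.integers(0, 2, n_trials),
        state2=rng.integers(0, 2, n_trials),
        choice2=rng.integers(0, 2, n_trials),
        reward=rng.integers(0, 2, n_trials),
    )
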