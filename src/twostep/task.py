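"""Two-step Markov decision task environment.

The task has a single first-stage state with two actions. Each first-stage
action leads to its commonly associated second-stage state with probability
``common_prob`` (default 0.7) and to the other state otherwise; the mapping
is fixed for a whole session (action 0 -> state 0, action 1 -> state 1).
Each of the two second-stage states offers two actions whose binary reward
probabilities drift across trials as independent Gaussian random walks with
reflecting boundaries (default 0.25 / 0.75).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "TaskConfig",
    "RewardSchedule",
    "build_reward_schedule",
    "sample_transition",
    "sample_reward",
    "block_of_trial",
]

N_ARMS = 4  # two second-stage states x two actions


@dataclass(frozen=True)
class TaskConfig:
    """Fixed structure of a two-step task session.

    Parameters
    ----------
    n_trials
        Number of main-task trials (default 201).
    common_prob
        Probability of the common first-stage transition, in (0.5, 1).
    walk_sd
        Standard deviation of each Gaussian random-walk step, in
        probability units per trial.
    walk_lo, walk_hi
        Reflecting boundaries of the reward-probability walks.
    reward_magnitude
        Monetary value of one rewarded trial (bookkeeping only; rewards
        enter learning as 0/1).
    break_after
        1-based trial indices after which a break occurs. Breaks are
        schedule markers only; the environment's dynamics are unchanged.
    n_practice
        Number of practice trials preceding the main task. Practice uses a
        separate stimulus set, so the main-task agent starts fresh; it is
        excluded from likelihood evaluation.
    rng_seed
        Default seed for schedule generation.
    """

    n_trials: int = 201
    common_prob: float = 0.7
    walk_sd: float = 0.025
    walk_lo: float = 0.25
    walk_hi: float = 0.75
    reward_magnitude: float = 0.20
    break_after: tuple[int, ...] = (67, 134)
    n_practice: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")
        if not 0.5 < self.common_prob < 1.0:
            raise ConfigError(
                f"common_prob must lie in (0.5, 1), got {self.common_prob}"
            )
        if not 0.0 < self.walk_lo < self.walk_hi < 1.0:
            raise ConfigError(
                "walk boundaries must satisfy 0 < walk_lo < walk_hi < 1, "
                f"got walk_lo={self.walk_lo}, walk_hi={self.walk_hi}"
            )
        if self.walk_sd < 0:
            raise ConfigError(f"walk_sd must be >= 0, got {self.walk_sd}")
        ba = tuple(self.break_after)
        object.__setattr__(self, "break_after", ba)
        if any(b2 <= b1 for b1, b2 in zip(ba, ba[1:])):
            raise ConfigError(f"break_after must be strictly increasing, got {ba}")
        if any(not 1 <= b < self.n_trials for b in ba):
            raise ConfigError(
                f"break_after entries must lie in [1, n_trials), got {ba}"
            )
        if self.n_practice < 0:
            raise ConfigError(f"n_practice must be >= 0, got {self.n_practice}")


@dataclass(frozen=True)
class RewardSchedule:
    """Reward probabilities for the four second-stage arms.

    ``probs`` has shape (4, n_trials); row ``2 * state + action`` holds the
    per-trial reward probability of that arm. Every entry lies within the
    reflecting boundaries of the walk that generated it.
    """

    probs: np.ndarray = field(repr=False)
    walk_lo: float = 0.25
    walk_hi: float = 0.75

    @property
    def n_trials(self) -> int:
        return self.probs.shape[1]

    def arm_prob(self, state2: int, action2: int, trial: int) -> float:
        return float(self.probs[2 * state2 + action2, trial])


def _reflect(x: float, lo: float, hi: float) -> float:
    # Mirror reflection at both bounds; loop handles overshoot past both.
    while x < lo or x > hi:
        if x > hi:
            x = 2.0 * hi - x
        elif x < lo:
            x = 2.0 * lo - x
    return x


def build_reward_schedule(config: TaskConfig, seed: int | None = None) -> RewardSchedule:
    """Generate the four reward-probability random walks for one session.

    Each arm starts at an independent uniform draw in
    [walk_lo, walk_hi] and then takes zero-mean Gaussian steps of SD
    ``walk_sd``, mirror-reflected at the boundaries. Deterministic given
    ``seed`` (falls back to ``config.rng_seed``).
    """
    if seed is None:
        seed = config.rng_seed
    rng = np.random.default_rng(seed)
    lo, hi = config.walk_lo, config.walk_hi
    probs = np.empty((N_ARMS, config.n_trials))
    start = rng.uniform(lo, hi, size=N_ARMS)
    steps = rng.normal(0.0, config.walk_sd, size=(N_ARMS, config.n_trials - 1))
    for arm in range(N_ARMS):
        x = float(start[arm])
        probs[arm, 0] = x
        for t in range(1, config.n_trials):
            x = _reflect(x + steps[arm, t - 1], lo, hi)
            probs[arm, t] = x
    return RewardSchedule(probs=probs, walk_lo=lo, walk_hi=hi)


def sample_transition(
    stage1_action: int, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Draw the second-stage state reached by a first-stage action.

    Action ``a`` transitions to its common state ``a`` with probability
    ``common_prob`` and to state ``1 - a`` otherwise.
    """
    if stage1_action not in (0, 1):
        raise InputError(f"stage1_action must be 0 or 1, got {stage1_action}")
    if rng.random() < config.common_prob:
        return stage1_action
    return 1 - stage1_action


def sample_reward(
    stage2_state: int,
    stage2_action: int,
    trial: int,
    schedule: RewardSchedule,
    rng: np.random.Generator,
) -> int:
    """Bernoulli reward (1/0) for an arm at a 0-based trial index."""
    if not 0 <= trial < schedule.n_trials:
        raise InputError(
            f"trial index {trial} out of range [0, {schedule.n_trials})"
        )
    if stage2_state not in (0, 1) or stage2_action not in (0, 1):
        raise InputError("stage2_state and stage2_action must be 0 or 1")
    p = schedule.arm_prob(stage2_state, stage2_action, trial)
    return int(rng.random() < p)


def block_of_trial(trial: int, break_after: tuple[int, ...]) -> int:
    """Block number (1-based) of a 1-based trial index given break positions."""
    if trial < 1:
        raise InputError(f"trial must be >= 1, got {trial}")
    return 1 + bisect.bisect_left(list(break_after), trial)
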