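"""Hybrid habitual / goal-directed reinforcement-learning agent.

The agent combines two valuation systems at the first stage of the
two-step task:

* a *model-free* (habitual) system learning stage-1 and stage-2 action
  values by SARSA(lambda) temporal-difference updates, and
* a *model-based* (goal-directed) system computing stage-1 values by
  Bellman evaluation of the known, fixed transition structure over the
  TD-learned stage-2 values.

Choice at stage 1 is a softmax over the weighted sum
``beta_hb * Q_MF + beta_gd * Q_MB + p * rep``, where ``rep`` indicates a
repeat of the previous first-stage choice; the two system weights double
as inverse temperatures. Stage 2 uses a single softmax with inverse
temperature ``beta2`` over the TD-learned values. The model has exactly
seven free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from . import _kernels
from .errors import ConfigError, DataError
from .task import RewardSchedule, TaskConfig, sample_reward, sample_transition

__all__ = [
    "ParameterSet",
    "AgentState",
    "SessionData",
    "model_based_values",
    "stage1_choice_probs",
    "stage2_choice_probs",
    "td_update",
    "simulate_session",
    "session_neg_log_likelihood",
]

Q_INIT_DEFAULT = 0.5  # midpoint of the {0, 1} outcome range


@dataclass(frozen=True)
class ParameterSet:
    """The seven free parameters of the hybrid model (natural scale).

    alpha1, alpha2 : stage-1 / stage-2 learning rates, in (0, 1)
    lam            : eligibility parameter coupling stage-2 reward
                     prediction errors to stage-1 values, in (0, 1)
    beta2          : stage-2 inverse temperature, >= 0
    beta_hb        : weight of the habitual (model-free) system, >= 0
    beta_gd        : weight of the goal-directed (model-based) system, >= 0
    p              : first-stage perseveration (stickiness), unbounded
    """

    alpha1: float
    alpha2: float
    lam: float
    beta2: float
    beta_hb: float
    beta_gd: float
    p: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        for name in ("beta2", "beta_hb", "beta_gd"):
            v = getattr(self, name)
            if v < 0.0:
                raise ConfigError(f"{name} must be >= 0, got {v}")

    @property
    def omega(self) -> float:
        """Derived relative goal-directed weight beta_gd / (beta_gd + beta_hb).

        Reported for description only; it is not a free parameter of the
        model and is never estimated directly.
        """
        tot = self.beta_gd + self.beta_hb
        return float("nan") if tot == 0 else self.beta_gd / tot

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha1, self.alpha2, self.lam, self.beta2, self.beta_hb,
             self.beta_gd, self.p]
        )


@dataclass(frozen=True)
class AgentState:
    """Learner state carried across trials within one session."""

    q_mf1: np.ndarray = field(default_factory=lambda: np.full(2, Q_INIT_DEFAULT))
    q2: np.ndarray = field(default_factory=lambda: np.full((2, 2), Q_INIT_DEFAULT))
    prev_choice1: int | None = None


@dataclass
class SessionData:
    """Ordered per-trial records of one subject-condition session."""

    subject_id: str
    condition: str
    choice1: np.ndarray
    state2: np.ndarray
    choice2: np.ndarray
    reward: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = {
            "choice1": self.choice1, "state2": self.state2,
            "choice2": self.choice2, "reward": self.reward,
        }
        n = len(self.choice1)
        for name, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 1 or len(arr) != n:
                raise DataError(f"{name} must be a 1-d array of length {n}")
            if not np.isin(arr, (0, 1)).all():
                raise DataError(f"{name} entries must all be 0 or 1")
            setattr(self, name, arr)
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if len(self.missing) != n:
                raise DataError("missing flags must match the trial count")

    @property
    def n_trials(self) -> int:
        return len(self.choice1)

    def to_frame(self, config: TaskConfig | None = None):
        """Long-format trial log with 1-based trial indices and block labels."""
        import pandas as pd

        from .task import block_of_trial

        break_after = config.break_after if config is not None else ()
        trials = np.arange(1, self.n_trials + 1)
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "condition": self.condition,
                "trial": trials,
                "choice1": self.choice1,
                "state2": self.state2,
                "choice2": self.choice2,
                "reward": self.reward,
                "block": [block_of_trial(int(t), break_after) for t in trials],
            }
        )


def model_based_values(q2: np.ndarray, common_prob: float = 0.7) -> np.ndarray:
    """Stage-1 values by Bellman evaluation of the fixed transition structure.

    ``Q_MB(a) = sum_s P(s | a) * max_a' q2[s, a']`` with
    ``P(state a | action a) = common_prob``.
    """
    q2 = np.asarray(q2, dtype=float)
    if q2.shape != (2, 2):
        raise DataError(f"q2 must have shape (2, 2), got {q2.shape}")
    state_max = q2.max(axis=1)
    rare = 1.0 - common_prob
    return np.array(
        [
            common_prob * state_max[0] + rare * state_max[1],
            common_prob * state_max[1] + rare * state_max[0],
        ]
    )


def _softmax_pair(logits: np.ndarray) -> np.ndarray:
    return np.exp(logits - logsumexp(logits))


def stage1_choice_probs(
    q_mf1: np.ndarray,
    q_mb1: np.ndarray,
    prev_choice1: int | None,
    params: ParameterSet,
) -> np.ndarray:
    """Softmax over the weighted sum of both systems plus perseveration."""
    logits = params.beta_hb * np.asarray(q_mf1, float) + params.beta_gd * np.asarray(
        q_mb1, float
    )
    if prev_choice1 is not None:
        rep = np.zeros(2)
        rep[prev_choice1] = 1.0
        logits = logits + params.p * rep
    return _softmax_pair(logits)


def stage2_choice_probs(q2_row: np.ndarray, beta2: float) -> np.ndarray:
    """Stage-2 softmax with inverse temperature ``beta2``."""
    return _softmax_pair(beta2 * np.asarray(q2_row, float))


def td_update(
    state: AgentState,
    choice1: int,
    state2: int,
    choice2: int,
    reward: float,
    params: ParameterSet,
) -> AgentState:
    """One SARSA(lambda) update from a completed trial; returns a new state.

    The stage-1 prediction error ``delta1`` uses the pre-update stage-2
    value of the visited arm; the stage-2 reward prediction error
    ``delta2`` then updates both the visited arm (by ``alpha2``) and,
    scaled by the eligibility parameter ``lam``, the chosen stage-1 value.
    """
    q_mf1 = state.q_mf1.copy()
    q2 = state.q2.copy()
    delta1 = q2[state2, choice2] - q_mf1[choice1]
    q_mf1[choice1] += params.alpha1 * delta1
    delta2 = reward - q2[state2, choice2]
    q2[state2, choice2] += params.alpha2 * delta2
    q_mf1[choice1] += params.alpha1 * params.lam * delta2
    return AgentState(q_mf1=q_mf1, q2=q2, prev_choice1=choice1)


def simulate_session(
    params: ParameterSet,
    config: TaskConfig,
    schedule: RewardSchedule,
    seed: int,
    subject_id: str = "sim",
    condition: str = "na",
    q_init: float = Q_INIT_DEFAULT,
) -> SessionData:
    """Generate one full session of choices from the hybrid agent.

    Alternates choice sampling and TD updating over ``config.n_trials``
    trials; deterministic given ``seed``.
    """
    if schedule.n_trials != config.n_trials:
        raise ConfigError(
            "schedule length does not match config.n_trials: "
            f"{schedule.n_trials} != {config.n_trials}"
        )
    rng = np.random.default_rng(seed)
    state = AgentState(
        q_mf1=np.full(2, q_init), q2=np.full((2, 2), q_init), prev_choice1=None
    )
    n = config.n_trials
    c1 = np.empty(n, dtype=np.int64)
    s2 = np.empty(n, dtype=np.int64)
    c2 = np.empty(n, dtype=np.int64)
    r = np.empty(n, dtype=np.int64)
    for t in range(n):
        q_mb1 = model_based_values(state.q2, config.common_prob)
        p1 = stage1_choice_probs(state.q_mf1, q_mb1, state.prev_choice1, params)
        c1[t] = int(rng.random() < p1[1])
        s2[t] = sample_transition(int(c1[t]), config, rng)
        p2 = stage2_choice_probs(state.q2[s2[t]], params.beta2)
        c2[t] = int(rng.random() < p2[1])
        r[t] = sample_reward(int(s2[t]), int(c2[t]), t, schedule, rng)
        state = td_update(state, int(c1[t]), int(s2[t]), int(c2[t]), float(r[t]), params)
    return SessionData(
        subject_id=subject_id, condition=condition,
        choice1=c1, state2=s2, choice2=c2, reward=r,
    )


def session_neg_log_likelihood(
    data: SessionData,
    params: ParameterSet,
    common_prob: float = 0.7,
    q_init: float = Q_INIT_DEFAULT,
) -> float:
    """Negative log likelihood of both choices on every non-missing trial.

    ``-sum_t [log P(choice1_t) + log P(choice2_t)]`` with the agent state
    updated trial by trial exactly as in :func:`td_update`. Trials flagged
    missing contribute nothing and trigger no update. Finite for all
    finite parameters.
    """
    return float(
        _kernels.session_nll(
            data.choice1, data.state2, data.choice2,
            data.reward.astype(np.float64), data.missing,
            params.alpha1, params.alpha2, params.lam,
            params.beta2, params.beta_hb, params.beta_gd, params.p,
            q_init, common_prob,
        )
    )
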