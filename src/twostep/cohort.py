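"""Synthetic study generator for the two-step break-activity design.

Emulates a within-subject experiment: each subject performs the task
twice (once per break condition, music vs. gaming, order
counterbalanced), has a working-memory covariate (a Digit Span-like
score), and generates behavior from subject-specific hybrid-model
parameters. The gaming condition can shift the unbounded goal-directed
weight by a main effect plus a working-memory interaction, which is the
structure the group-level moderation analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import ParameterSet, simulate_session
from .errors import ConfigError
from .estimation import PARAM_NAMES, to_natural
from .task import TaskConfig, build_reward_schedule

__all__ = ["CohortConfig", "SubjectRecord", "draw_cohort", "generate_cohort_sessions"]

# Population means / between-subject SDs of the seven parameters on the
# unbounded scale. Chosen so that the implied natural-scale medians sit
# inside plausible interquartile ranges for healthy adults on this task
# (e.g. median learning rates ~0.6-0.8, softmax weights ~2.5-3.3).
_POP_MEAN_DEFAULT = (0.4, 0.7, 1.3, 1.1, 0.9, 1.2, 0.75)
_POP_SD_DEFAULT = (1.0, 0.6, 1.0, 0.4, 0.5, 0.6, 0.5)

_BETA_GD_IDX = PARAM_NAMES.index("beta_gd")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level generator settings.

    The working-memory covariate emulates the backwards Digit Span
    (mean 7.39, SD 1.78 for a 33-subject cohort). The default condition
    effects on the unbounded goal-directed weight reproduce the
    qualitative moderation pattern of interest: a small overall gaming
    decrement that is concentrated in low-working-memory subjects
    (main effect -0.17, interaction +0.24 per SD of working memory, so
    the simple gaming effect is -0.41 one SD below the mean and near
    zero one SD above).
    """

    n_subjects: int = 33
    conditions: tuple[str, str] = ("music", "gaming")
    wm_mean: float = 7.39
    wm_sd: float = 1.78
    pop_mean: tuple[float, ...] = _POP_MEAN_DEFAULT
    pop_sd: tuple[float, ...] = _POP_SD_DEFAULT
    session_sd: float = 0.0
    effect_beta_gd_condition: float = -0.17
    effect_beta_gd_interaction: float = 0.24
    counterbalance: bool = True
    round_wm: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ConfigError("exactly two distinct conditions are required")
        if self.wm_sd < 0 or self.session_sd < 0:
            raise ConfigError("SDs must be >= 0")
        if len(self.pop_mean) != 7 or len(self.pop_sd) != 7:
            raise ConfigError("pop_mean and pop_sd must each have 7 entries")
        if any(s < 0 for s in self.pop_sd):
            raise ConfigError("pop_sd entries must be >= 0")


@dataclass
class SubjectRecord:
    """One simulated subject: covariates and true per-condition parameters."""

    subject_id: str
    wm_score: float
    z_wm: float
    speed: float
    condition_order: tuple[str, str]
    true_unbounded: dict[str, np.ndarray] = field(default_factory=dict)

    def true_params(self, condition: str) -> ParameterSet:
        return to_natural(self.true_unbounded[condition])


def draw_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw subjects, covariates and condition-specific true parameters.

    Subject-level unbounded parameters are Normal(pop_mean, pop_sd); per
    condition they optionally receive independent Normal(0, session_sd)
    session-to-session perturbations, and the gaming condition's
    unbounded goal-directed weight is additionally shifted by
    ``effect_beta_gd_condition + effect_beta_gd_interaction * z_wm``.
    Condition order alternates across subjects when counterbalancing is
    on. Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_subjects
    wm = rng.normal(config.wm_mean, config.wm_sd, size=n)
    if config.round_wm:
        wm = np.round(wm)
    z_wm = (wm - wm.mean()) / wm.std(ddof=1)
    speed = rng.normal(0.0, 1.0, size=n)
    base = rng.normal(
        np.asarray(config.pop_mean), np.asarray(config.pop_sd), size=(n, 7)
    )
    music, gaming = config.conditions
    records: list[SubjectRecord] = []
    for i in range(n):
        per_cond: dict[str, np.ndarray] = {}
        for cond in config.conditions:
            u = base[i].copy()
            if config.session_sd > 0:
                u = u + rng.normal(0.0, config.session_sd, size=7)
            if cond == gaming:
                u[_BETA_GD_IDX] += (
                    config.effect_beta_gd_condition
                    + config.effect_beta_gd_interaction * z_wm[i]
                )
            per_cond[cond] = u
        if config.counterbalance and i % 2 == 1:
            order = (gaming, music)
        else:
            order = (music, gaming)
        records.append(
            SubjectRecord(
                subject_id=f"s{i + 1:03d}",
                wm_score=float(wm[i]),
                z_wm=float(z_wm[i]),
                speed=float(speed[i]),
                condition_order=order,
                true_unbounded=per_cond,
            )
        )
    return records


def generate_cohort_sessions(
    records: list[SubjectRecord],
    task_config: TaskConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Simulate every subject-condition session of a drawn cohort.

    Each session gets a fresh reward schedule and its own derived seed.
    Returns the long-format trial log, the subject covariate table, and
    the list of :class:`~twostep.agent.SessionData` objects in
    generation order.
    """
    from .seeding import derive_seed

    frames = []
    sessions = []
    for rec in records:
        for cond in rec.condition_order:
            sched_seed = derive_seed(seed, "schedule", rec.subject_id, cond)
            sim_seed = derive_seed(seed, "simulate", rec.subject_id, cond)
            schedule = build_reward_schedule(task_config, sched_seed)
            session = simulate_session(
                rec.true_params(cond), task_config, schedule, sim_seed,
                subject_id=rec.subject_id, condition=cond,
            )
            sessions.append(session)
            frames.append(session.to_frame(task_config))
    trials = pd.concat(frames, ignore_index=True)
    covariates = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "wm_score": [r.wm_score for r in records],
            "z_wm": [r.z_wm for r in records],
            "speed": [r.speed for r in records],
            "condition_order": ["/".join(r.condition_order) for r in records],
        }
    )
    return trials, covariates, sessions
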