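"""CSV interchange for trial logs, covariates and fitted-parameter tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .agent import SessionData
from .errors import DataError
from .estimation import FitResult

TRIAL_LOG_COLUMNS = [
    "subject_id", "condition", "trial", "choice1", "state2", "choice2",
    "reward", "block",
]

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "write_trial_log",
    "read_trial_log",
    "sessions_from_frame",
    "fits_to_frame",
]


def write_trial_log(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial log is missing columns {missing}")
    trials[TRIAL_LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial log at {path} is missing columns {missing}")
    return trials


def sessions_from_frame(trials: pd.DataFrame) -> list[SessionData]:
    """Split a long-format trial log into per-session records."""
    sessions = []
    for (subject_id, condition), g in trials.groupby(
        ["subject_id", "condition"], sort=False
    ):
        g = g.sort_values("trial")
        sessions.append(
            SessionData(
                subject_id=str(subject_id), condition=str(condition),
                choice1=g["choice1"].to_numpy(),
                state2=g["state2"].to_numpy(),
                choice2=g["choice2"].to_numpy(),
                reward=g["reward"].to_numpy(),
            )
        )
    return sessions


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    """Parameter table with natural and unbounded (``u_``-prefixed) columns."""
    return pd.DataFrame([f.as_row() for f in fits])
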