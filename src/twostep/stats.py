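"""Group-level inference on fitted model parameters.

Linear mixed-effects models (random subject intercepts) test the effect
of break condition on each parameter, optionally moderated by a z-scored
working-memory covariate, with simple effects obtained by re-centering
the moderator at +/- 1 SD. Directed hypotheses use one-tailed tests;
exploratory families are Bonferroni corrected. Condition coding is
music = 0 (reference), gaming = 1, so a negative coefficient means a
gaming-related reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DataError, DegenerateDesignError, InferenceError, InputError

__all__ = [
    "TestResult",
    "fit_condition_model",
    "fit_moderation_model",
    "simple_effects",
    "bonferroni",
    "paired_t",
    "stay_probability_table",
    "CONDITION_CODING",
]

CONDITION_CODING = {"music": 0.0, "gaming": 1.0}


@dataclass
class TestResult:
    """One coefficient test from a fitted model."""

    name: str
    b: float
    se: float
    df: float
    t: float
    p: float
    tails: str
    formula: str = ""
    p_adjusted: float | None = None

    def as_row(self) -> dict:
        return {
            "test": self.name, "b": self.b, "se": self.se, "df": self.df,
            "t": self.t, "p": self.p, "p_adjusted": self.p_adjusted,
            "tails": self.tails, "formula": self.formula,
        }


def _p_from_t(t: float, df: float, tails: str) -> float:
    if tails == "two":
        return float(2.0 * sps.t.sf(abs(t), df))
    if tails == "less":  # H1: coefficient < 0
        return float(sps.t.cdf(t, df))
    if tails == "greater":  # H1: coefficient > 0
        return float(sps.t.sf(t, df))
    raise InputError(f"tails must be 'two', 'less' or 'greater', got {tails!r}")


def _prepare(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    if parameter not in table.columns:
        raise InferenceError(f"parameter column {parameter!r} not in table")
    df = table.copy()
    if df[parameter].isna().any():
        raise DataError(f"missing values in parameter column {parameter!r}")
    if df["subject_id"].nunique() < 3:
        raise InferenceError("at least 3 subjects are required for inference")
    if "cond" not in df.columns:
        codes = df["condition"].map(CONDITION_CODING)
        if codes.isna().any():
            # arbitrary two-level factor: first level sorted = reference
            levels = sorted(df["condition"].unique())
            codes = df["condition"].map({lv: float(i) for i, lv in enumerate(levels)})
        df["cond"] = codes.astype(float)
    if df["cond"].nunique() < 2:
        raise DegenerateDesignError("condition column is constant")
    return df


def _fit_mixed(df: pd.DataFrame, formula: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        res = None
        last_err: Exception | None = None
        # the profiled REML objective can be numerically singular near the
        # zero-variance boundary; fall back through sturdier optimizers
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
        if res is None:
            raise InferenceError(f"mixed model failed to fit: {last_err}")
    n_obs = len(df)
    k_fixed = model.exog.shape[1]
    n_groups = df["subject_id"].nunique()
    # residual df after fixed effects and (n_groups - 1) intercept deviations
    df_resid = n_obs - k_fixed - (n_groups - 1)
    if df_resid < 1:
        raise InferenceError("non-positive residual degrees of freedom")
    return res, float(df_resid)


def _coef_test(res, df_resid: float, term: str, tails: str, name: str,
               formula: str) -> TestResult:
    b = float(res.fe_params[term])
    se = float(res.bse_fe[term])
    t = b / se
    return TestResult(
        name=name, b=b, se=se, df=df_resid, t=t,
        p=_p_from_t(t, df_resid, tails), tails=tails, formula=formula,
    )


def fit_condition_model(
    table: pd.DataFrame, parameter: str, one_tailed: str | None = None
) -> TestResult:
    """Mixed model ``parameter ~ condition + (1 | subject)``.

    With exactly two observations per subject the condition coefficient
    equals the paired mean difference (gaming minus music).
    """
    df = _prepare(table, parameter)
    tails = one_tailed if one_tailed is not None else "two"
    formula = f"{parameter} ~ cond"
    res, df_resid = _fit_mixed(df, formula)
    return _coef_test(res, df_resid, "cond", tails, "condition", formula)


def _zscore_moderator(df: pd.DataFrame, moderator: str) -> pd.Series:
    # moderator is a between-subject covariate: z-score over subjects
    per_subj = df.groupby("subject_id")[moderator].first()
    if per_subj.std(ddof=1) == 0:
        raise DegenerateDesignError(f"moderator {moderator!r} is constant")
    z = (per_subj - per_subj.mean()) / per_subj.std(ddof=1)
    return df["subject_id"].map(z).astype(float)


def fit_moderation_model(
    table: pd.DataFrame,
    parameter: str,
    moderator: str = "wm_score",
    covariates: tuple[str, ...] = (),
    one_tailed: str | dict | None = None,
    moderator_shift: float = 0.0,
) -> dict[str, TestResult]:
    """Mixed model with a condition-by-moderator interaction.

    ``parameter ~ condition * z(moderator) + covariates + (1 | subject)``.
    The moderator is z-scored across subjects so coefficients are
    standardized; ``moderator_shift`` re-centers the z-scored moderator
    (subtracting the shift), which makes the condition coefficient the
    simple condition effect at that moderator value. ``one_tailed`` may
    be a single direction applied to condition and interaction, or a
    mapping like ``{"condition": "less", "interaction": "greater"}``.
    Returns tests for the condition simple effect, the moderator slope,
    the interaction, and each covariate.
    """
    df = _prepare(table, parameter)
    if moderator not in df.columns:
        raise InferenceError(f"moderator column {moderator!r} not in table")
    df["z_mod"] = _zscore_moderator(df, moderator) - moderator_shift
    terms = ["cond", "z_mod", "cond:z_mod", *covariates]
    rhs = " + ".join(["cond * z_mod", *covariates])
    formula = f"{parameter} ~ {rhs}"
    for cov in covariates:
        if cov not in df.columns:
            raise InferenceError(f"covariate column {cov!r} not in table")
    X = np.column_stack([np.ones(len(df))] + [
        df["cond"], df["z_mod"], df["cond"] * df["z_mod"],
        *[df[c] for c in covariates],
    ])
    cond_number = np.linalg.cond(X)
    if cond_number > 1e8:
        warnings.warn(
            f"design matrix is ill-conditioned (condition number {cond_number:.3g})",
            UserWarning, stacklevel=2,
        )
    res, df_resid = _fit_mixed(df, formula)
    if one_tailed is None:
        tails = {"condition": "two", "interaction": "two"}
    elif isinstance(one_tailed, str):
        tails = {"condition": one_tailed, "interaction": one_tailed}
    else:
        tails = {"condition": one_tailed.get("condition", "two"),
                 "interaction": one_tailed.get("interaction", "two")}
    out = {
        "condition": _coef_test(
            res, df_resid, "cond", tails["condition"], "condition", formula
        ),
        "moderator": _coef_test(res, df_resid, "z_mod", "two", "moderator", formula),
        "interaction": _coef_test(
            res, df_resid, "cond:z_mod", tails["interaction"], "interaction", formula
        ),
    }
    for cov in covariates:
        out[cov] = _coef_test(res, df_resid, cov, "two", cov, formula)
    return out


def simple_effects(
    table: pd.DataFrame,
    parameter: str,
    moderator: str = "wm_score",
    at_sd: float = -1.0,
    covariates: tuple[str, ...] = (),
    one_tailed: str | None = None,
) -> TestResult:
    """Condition effect at ``moderator = at_sd`` SDs from its mean.

    Implemented by re-centering the z-scored moderator so that the
    condition main effect of the refitted moderation model is the simple
    effect at the requested moderator value. The identity
    ``simple(+1) - simple(-1) = 2 * interaction`` holds by construction.
    """
    fits = fit_moderation_model(
        table, parameter, moderator=moderator, covariates=covariates,
        one_tailed=one_tailed, moderator_shift=at_sd,
    )
    result = fits["condition"]
    result.name = f"condition at z={at_sd:+g}"
    return result


def bonferroni(p_values, m: int) -> list[float]:
    """Bonferroni adjustment: ``min(1, m * p)`` for each p."""
    p_values = list(p_values)
    if m < len(p_values):
        raise InputError(
            f"correction family size m={m} is smaller than the number of tests "
            f"({len(p_values)})"
        )
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise InputError(f"p values must lie in [0, 1], got {p}")
    return [min(1.0, m * p) for p in p_values]


def paired_t(values_a, values_b, tails: str = "two") -> TestResult:
    """Classic paired t-test of ``a - b``.

    A zero-variance difference is handled explicitly: t = 0, p = 1 when
    the vectors are identical; |t| = inf, p = 0 (two-tailed) for a
    constant nonzero shift.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired_t requires two 1-d vectors of equal length")
    n = len(a)
    if n < 3:
        raise InputError(f"paired_t requires n >= 3, got {n}")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            t, p = 0.0, 1.0 if tails == "two" else 0.5
        else:
            t = np.inf if md > 0 else -np.inf
            p = _p_from_t(t, df, tails)
        return TestResult("paired_t", md, 0.0, df, t, p, tails)
    se = sd / np.sqrt(n)
    t = md / se
    return TestResult("paired_t", float(md), float(se), df, float(t),
                      _p_from_t(float(t), df, tails), tails)


def stay_probability_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Stay probabilities by previous reward x previous transition type.

    For each session (subject-condition), a trial "stays" when its
    first-stage choice repeats the previous trial's. The previous
    transition is common when the previous second-stage state equals the
    previous first-stage choice's commonly associated state. Cells with
    no observations are reported as NaN, never imputed. This 2x2 table
    is the standard behavioral signature: a pure habitual learner shows
    a main effect of previous reward, a goal-directed learner a
    reward-by-transition interaction.
    """
    required = {"subject_id", "condition", "trial", "choice1", "state2", "reward"}
    if not required.issubset(trials.columns):
        raise DataError(f"trial log must contain columns {sorted(required)}")
    rows = []
    for (_, _), g in trials.groupby(["subject_id", "condition"], sort=False):
        g = g.sort_values("trial")
        if len(g) < 2:
            raise DataError("stay probabilities need at least 2 trials per session")
        c1 = g["choice1"].to_numpy()
        s2 = g["state2"].to_numpy()
        r = g["reward"].to_numpy()
        stay = (c1[1:] == c1[:-1]).astype(float)
        prev_reward = r[:-1]
        prev_common = (s2[:-1] == c1[:-1]).astype(int)
        rows.append(pd.DataFrame({
            "stay": stay, "prev_reward": prev_reward, "prev_common": prev_common,
        }))
    pooled = pd.concat(rows, ignore_index=True)
    table = (
        pooled.groupby(["prev_reward", "prev_common"])["stay"]
        .mean()
        .reindex(pd.MultiIndex.from_product(
            [[0, 1], [0, 1]], names=["prev_reward", "prev_common"]
        ))
        .unstack("prev_common")
    )
    table.columns = ["rare" if c == 0 else "common" for c in table.columns]
    table.index = ["unrewarded" if i == 0 else "rewarded" for i in table.index]
    return table
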