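"""MAP estimation of the hybrid model on an unbounded parameter scale.

Bounded parameters are transformed to the real line — logit for the
learning rates and the eligibility parameter, log for the three softmax
weights, identity for the perseveration parameter — and the posterior
(likelihood times an uncorrelated Gaussian prior on the transformed
scale) is maximized by quasi-Newton optimization from several random
starting points. A one-step empirical-Bayes EM variant re-estimates the
prior from the population of per-session estimates and refits once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .agent import ParameterSet, SessionData, session_neg_log_likelihood
from .errors import FittingError, InputError

__all__ = [
    "PARAM_NAMES",
    "Prior",
    "FitResult",
    "to_unbounded",
    "to_natural",
    "broad_prior",
    "neg_log_posterior",
    "fit_map",
    "laplace_variances",
    "em_prior_step",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("alpha1", "alpha2", "lam", "beta2", "beta_hb", "beta_gd", "p")
N_PARAMS = len(PARAM_NAMES)

_LOGIT_IDX = slice(0, 3)   # alpha1, alpha2, lam
_LOG_IDX = slice(3, 6)     # beta2, beta_hb, beta_gd
# p (index 6) uses the identity transform.

# Guards keeping the likelihood finite at extreme unbounded values during
# optimization: exp is capped and the logistic output kept inside the open
# unit interval. Both bind far outside the region any fit settles in.
_MAX_LOG_BETA = 50.0
_UNIT_EPS = 1e-15


def to_unbounded(params: ParameterSet) -> np.ndarray:
    """Map natural parameters to the estimation scale (logit / log / identity)."""
    x = params.as_array()
    if np.any(x[_LOG_IDX] <= 0.0):
        raise InputError("beta parameters must be strictly positive to transform")
    u = np.empty(N_PARAMS)
    u[_LOGIT_IDX] = logit(x[_LOGIT_IDX])
    u[_LOG_IDX] = np.log(x[_LOG_IDX])
    u[6] = x[6]
    return u


def to_natural(u: np.ndarray) -> ParameterSet:
    """Inverse transform: logistic for rates, exp for weights, identity for p."""
    u = np.asarray(u, dtype=float)
    if u.shape != (N_PARAMS,):
        raise InputError(f"expected {N_PARAMS} unbounded parameters, got {u.shape}")
    bounded = np.clip(expit(u[_LOGIT_IDX]), _UNIT_EPS, 1.0 - _UNIT_EPS)
    betas = np.exp(np.minimum(u[_LOG_IDX], _MAX_LOG_BETA))
    return ParameterSet(
        alpha1=float(bounded[0]), alpha2=float(bounded[1]), lam=float(bounded[2]),
        beta2=float(betas[0]), beta_hb=float(betas[1]), beta_gd=float(betas[2]),
        p=float(u[6]),
    )


@dataclass(frozen=True)
class Prior:
    """Uncorrelated Gaussian prior on the unbounded scale."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (N_PARAMS,) or sd.shape != (N_PARAMS,):
            raise InputError(f"prior mean and sd must each have {N_PARAMS} entries")
        if np.any(sd <= 0):
            raise InputError("prior SDs must all be > 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    def penalty(self, u: np.ndarray) -> float:
        """Gaussian negative log density without its additive constant."""
        z = (np.asarray(u, float) - self.mean) / self.sd
        return float(0.5 * np.dot(z, z))


def broad_prior(sd: float = 100.0) -> Prior:
    """The default near-flat prior: mean 0, SD 100 on every parameter."""
    return Prior(mean=np.zeros(N_PARAMS), sd=np.full(N_PARAMS, sd))


@dataclass
class FitResult:
    """Outcome of one per-session MAP fit."""

    subject_id: str
    condition: str
    map_unbounded: np.ndarray
    map_natural: ParameterSet
    neg_log_posterior: float
    n_restarts: int
    converged: bool
    best_restart: int
    # (objective at start, objective at optimum) per restart
    restart_objectives: list[tuple[float, float]] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "condition": self.condition}
        for name, value in zip(PARAM_NAMES, self.map_natural.as_array()):
            row[name] = float(value)
        for name, value in zip(PARAM_NAMES, self.map_unbounded):
            row[f"u_{name}"] = float(value)
        row["nlp"] = self.neg_log_posterior
        row["converged"] = self.converged
        return row


def neg_log_posterior(
    data: SessionData,
    u: np.ndarray,
    prior: Prior,
    common_prob: float = 0.7,
) -> float:
    """Session NLL plus the Gaussian prior penalty (constants dropped).

    Additive normalization constants of the prior are omitted — they do
    not move the argmax — so absolute objective values are comparable
    only within this package.
    """
    return session_neg_log_likelihood(data, to_natural(u), common_prob) + prior.penalty(u)


def fit_map(
    data: SessionData,
    prior: Prior | None = None,
    n_restarts: int = 6,
    restart_sd: float = 0.1,
    seed: int = 0,
    common_prob: float = 0.7,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> FitResult:
    """MAP fit by multistart quasi-Newton optimization on the unbounded scale.

    Starting points are drawn Normal(0, restart_sd) independently per
    parameter; the restart reaching the lowest negative log posterior
    wins. Deterministic given ``seed``.
    """
    if data.n_trials == 0:
        raise InputError("cannot fit an empty session")
    if n_restarts < 1:
        raise InputError(f"n_restarts must be >= 1, got {n_restarts}")
    if prior is None:
        prior = broad_prior()
    rng = np.random.default_rng(seed)

    def objective(u: np.ndarray) -> float:
        val = neg_log_posterior(data, u, prior, common_prob)
        return val if np.isfinite(val) else 1e30

    best = None
    any_converged = False
    trajectories: list[tuple[float, float]] = []
    for restart in range(n_restarts):
        u0 = rng.normal(0.0, restart_sd, size=N_PARAMS)
        f0 = neg_log_posterior(data, u0, prior, common_prob)
        for _ in range(50):
            if np.isfinite(f0):
                break
            logger.warning("non-finite objective at start, redrawing (restart %d)", restart)
            u0 = rng.normal(0.0, restart_sd, size=N_PARAMS)
            f0 = neg_log_posterior(data, u0, prior, common_prob)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                objective, u0, method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
        # BFGS with finite-difference gradients often stops with a
        # "precision loss" status at an otherwise good optimum; accept the
        # iterate as converged when the remaining gradient is small.
        ok = bool(res.success) or (
            res.jac is not None and np.abs(res.jac).max() < 1e-3
        )
        any_converged = any_converged or ok
        trajectories.append((float(f0), float(res.fun)))
        if np.isfinite(res.fun) and (best is None or res.fun < best[1]):
            best = (res.x, float(res.fun), restart)
    if best is None:
        raise FittingError(
            f"all {n_restarts} restarts returned a non-finite optimum for "
            f"session {data.subject_id}/{data.condition}"
        )
    u_hat, nlp, which = best
    if not any_converged:
        logger.warning(
            "no restart reported convergence for %s/%s; returning best iterate",
            data.subject_id, data.condition,
        )
    return FitResult(
        subject_id=data.subject_id, condition=data.condition,
        map_unbounded=u_hat, map_natural=to_natural(u_hat),
        neg_log_posterior=nlp, n_restarts=n_restarts,
        converged=any_converged, best_restart=which,
        restart_objectives=trajectories,
    )


def laplace_variances(
    data: SessionData,
    u: np.ndarray,
    prior: Prior,
    common_prob: float = 0.7,
    h: float = 1e-3,
    min_curvature: float = 1e-2,
) -> np.ndarray:
    """Diagonal Laplace-approximation variances at a mode.

    Second derivatives of the negative log posterior are taken by central
    differences per coordinate; curvatures below ``min_curvature`` are
    floored so flat directions yield large but finite variances.
    """
    f0 = neg_log_posterior(data, u, prior, common_prob)
    var = np.empty(N_PARAMS)
    for i in range(N_PARAMS):
        e = np.zeros(N_PARAMS)
        e[i] = h
        d2 = (
            neg_log_posterior(data, u + e, prior, common_prob)
            - 2.0 * f0
            + neg_log_posterior(data, u - e, prior, common_prob)
        ) / h**2
        var[i] = 1.0 / max(d2, min_curvature)
    return var


def em_prior_step(
    fits: list[FitResult],
    datasets: list[SessionData],
    include_laplace: bool = True,
    var_floor: float = 1e-4,
    n_restarts: int = 6,
    restart_sd: float = 0.1,
    seed: int = 0,
    common_prob: float = 0.7,
) -> tuple[Prior, list[FitResult]]:
    """One empirical-Bayes EM iteration: re-estimate the prior, refit once.

    The new prior mean is the sample mean of the unbounded MAP estimates
    across sessions (sessions of the same subject treated as
    independent); the prior variance is their sample variance, optionally
    inflated by the mean per-fit Laplace variance, floored at
    ``var_floor``. Every session is then refit once under the new prior.
    """
    if len(fits) == 0:
        raise InputError("em_prior_step requires at least one fit")
    if len(fits) < 2:
        raise InputError("em_prior_step requires >= 2 sessions to estimate a prior")
    if len(fits) != len(datasets):
        raise InputError("fits and datasets must align one-to-one")
    U = np.stack([f.map_unbounded for f in fits])
    mean = U.mean(axis=0)
    var = U.var(axis=0, ddof=1)
    if include_laplace:
        old_prior = broad_prior()
        lap = np.stack(
            [laplace_variances(d, f.map_unbounded, old_prior, common_prob)
             for f, d in zip(fits, datasets)]
        )
        var = var + lap.mean(axis=0)
    floored = var < var_floor
    if floored.any():
        logger.warning(
            "EM prior variance floored for: %s",
            [PARAM_NAMES[i] for i in np.flatnonzero(floored)],
        )
        var = np.maximum(var, var_floor)
    new_prior = Prior(mean=mean, sd=np.sqrt(var))
    refits = [
        fit_map(
            d, prior=new_prior, n_restarts=n_restarts, restart_sd=restart_sd,
            seed=seed + i, common_prob=common_prob,
        )
        for i, d in enumerate(datasets)
    ]
    return new_prior, refits
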