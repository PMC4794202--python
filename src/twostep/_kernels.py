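"""Compiled inner loops for likelihood evaluation.

The session likelihood is inherently sequential (the agent's Q-values are
updated trial by trial), so it is expressed as an explicit loop and JIT
compiled with numba. MAP fitting evaluates this function thousands of
times per session; everything else in the package calls it through
:func:`twostep.agent.session_neg_log_likelihood`.
"""

from __future__ import annotations

import math

import numba
import numpy as np


@numba.njit(cache=True)
def session_nll(
    choice1: np.ndarray,
    state2: np.ndarray,
    choice2: np.ndarray,
    reward: np.ndarray,
    missing: np.ndarray,
    alpha1: float,
    alpha2: float,
    lam: float,
    beta2: float,
    beta_hb: float,
    beta_gd: float,
    p: float,
    q_init: float,
    common_prob: float,
) -> float:  # pragma: no cover - exercised via the python wrapper
    q_mf1 = np.full(2, q_init)
    q2 = np.full((2, 2), q_init)
    prev_choice1 = -1
    nll = 0.0
    rare = 1.0 - common_prob
    for t in range(choice1.shape[0]):
        if missing[t]:
            continue
        c1 = choice1[t]
        s2 = state2[t]
        c2 = choice2[t]
        r = reward[t]

        # model-based stage-1 values from the known transition structure
        max0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        max1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        qmb0 = common_prob * max0 + rare * max1
        qmb1 = common_prob * max1 + rare * max0

        # stage-1 softmax with perseveration, stabilized by max subtraction
        x0 = beta_hb * q_mf1[0] + beta_gd * qmb0
        x1 = beta_hb * q_mf1[1] + beta_gd * qmb1
        if prev_choice1 == 0:
            x0 += p
        elif prev_choice1 == 1:
            x1 += p
        m = x0 if x0 >= x1 else x1
        lse = m + math.log(math.exp(x0 - m) + math.exp(x1 - m))
        nll -= (x0 if c1 == 0 else x1) - lse

        # stage-2 softmax under beta2
        y0 = beta2 * q2[s2, 0]
        y1 = beta2 * q2[s2, 1]
        m2 = y0 if y0 >= y1 else y1
        lse2 = m2 + math.log(math.exp(y0 - m2) + math.exp(y1 - m2))
        nll -= (y0 if c2 == 0 else y1) - lse2

        # SARSA(lambda) temporal-difference update
        delta1 = q2[s2, c2] - q_mf1[c1]
        q_mf1[c1] += alpha1 * delta1
        delta2 = r - q2[s2, c2]
        q2[s2, c2] += alpha2 * delta2
        q_mf1[c1] += alpha1 * lam * delta2
        prev_choice1 = c1
    return nll
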