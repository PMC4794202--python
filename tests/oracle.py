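"""Independent brute-force oracle for the hybrid agent's session likelihood.

A deliberately literal transliteration of the generative model, written
with plain dictionaries, lists and explicit arithmetic — no shared code
with the package implementation — so that agreement between the two is a
meaningful check.
"""

import math


def softmax2(x0, x1):
    m = max(x0, x1)
    e0 = math.exp(x0 - m)
    e1 = math.exp(x1 - m)
    return e0 / (e0 + e1), e1 / (e0 + e1)


def oracle_session_nll(trials, params, common_prob=0.7, q_init=0.5,
                       verbose=False):
    """Negative log likelihood computed trial by trial.

    ``trials`` is a list of dicts with keys choice1, state2, choice2,
    reward (and optionally ``missing``); ``params`` is a dict with keys
    alpha1, alpha2, lam, beta2, beta_hb, beta_gd, p.
    """
    q_mf1 = {0: q_init, 1: q_init}
    q2 = {(0, 0): q_init, (0, 1): q_init, (1, 0): q_init, (1, 1): q_init}
    prev = None
    nll = 0.0
    for t, trial in enumerate(trials):
        if trial.get("missing", False):
            continue
        c1, s2, c2, r = (trial["choice1"], trial["state2"], trial["choice2"],
                         trial["reward"])

        # goal-directed values: expectation of the better stage-2 option
        # under the fixed transition structure (action a commonly -> state a)
        best = {s: max(q2[(s, 0)], q2[(s, 1)]) for s in (0, 1)}
        q_mb = {
            0: common_prob * best[0] + (1 - common_prob) * best[1],
            1: common_prob * best[1] + (1 - common_prob) * best[0],
        }

        logits = {}
        for a in (0, 1):
            logits[a] = (params["beta_hb"] * q_mf1[a]
                         + params["beta_gd"] * q_mb[a]
                         + (params["p"] if prev == a else 0.0))
        p1 = softmax2(logits[0], logits[1])
        p2 = softmax2(params["beta2"] * q2[(s2, 0)],
                      params["beta2"] * q2[(s2, 1)])
        if verbose:
            print(f"trial {t}: P(stage1)={p1}, P(stage2|state {s2})={p2}")
        nll -= math.log(p1[c1]) + math.log(p2[c2])

        delta1 = q2[(s2, c2)] - q_mf1[c1]
        q_mf1[c1] = q_mf1[c1] + params["alpha1"] * delta1
        delta2 = r - q2[(s2, c2)]
        q2[(s2, c2)] = q2[(s2, c2)] + params["alpha2"] * delta2
        q_mf1[c1] = q_mf1[c1] + params["alpha1"] * params["lam"] * delta2
        prev = c1
    return nll
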