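# Methods

## Task environment

The environment implements the fixed two-step structure: two first-stage
actions, two second-stage states, a 0.7/0.3 transition matrix with the
mapping action 0 → state 0, action 1 → state 1 held fixed for a whole
session, and four second-stage reward probabilities following
independent Gaussian random walks mirror-reflected at 0.25/0.75
(`x → 2·bound − x`, applied repeatedly so overshoot past both bounds is
handled). Reflection rather than clipping keeps the walk's stationary
distribution roughly uniform over the band instead of piling mass at the
boundaries. Sessions default to 201 trials with break markers after
trials 67 and 134 (1-based); breaks label blocks in the trial log but do
not alter the dynamics, and the perseveration indicator is deliberately
not reset at breaks (configurable in principle via the trial log's block
column, but no analysis here uses it).

Two environment settings are conventions rather than published values:
the walk step SD (0.025) and the walk initialization (uniform on the
reflecting band, independently per arm). Both are exposed on
`TaskConfig`. The 50 practice trials use a separate stimulus set, so
learned values do not carry over; the package therefore starts each main
session from fresh values and does not simulate practice.

## Agent

Q-values initialize at 0.5, the midpoint of the {0, 1} outcome range, so
the first trial is uninformative for both systems (configurable via
`q_init`). The two systems share the stage-2 values and temperature β₂
and differ only at stage 1, where the model-free values come from
SARSA(λ) and the model-based values from Bellman evaluation of the true
transition matrix (taken as known, not learned). There is no separate
stage-1 temperature: β_HB and β_GD jointly set both the mixture and the
determinism of stage-1 choice. Perseveration applies at stage 1 only.
All softmaxes subtract the maximum logit before exponentiating, so the
likelihood is finite for arbitrarily large weights.

With rewards in {0, 1} and initialization inside [0, 1], every TD update
is a convex combination, so stage-2 values remain in [0, 1] for all
α₂ ∈ (0, 1); this is enforced as a property test.

The likelihood loop is sequential by nature and is JIT-compiled with
numba; the test suite checks it against an independently written
pure-Python trial-by-trial oracle to 1e-10.

## Estimation

Bounded parameters are estimated on an unbounded scale: u = logit(x) for
α₁, α₂, λ; u = log(β) for the three weights (so β = exp(u) > 0 always);
p is already unbounded. The objective is the session NLL plus the
Gaussian prior penalty Σ (uᵢ − mᵢ)²/(2 sᵢ²); the prior's additive
normalization constants are dropped, so printed objective values are
comparable only within this package. Default prior: mean 0, SD 100 per
parameter — near-flat, so the MAP is essentially the MLE whenever the
data identify the parameters.

Optimization is multistart BFGS with numerical gradients (start values
Normal(0, 0.1), 6 restarts, gtol 1e-6, 500 iterations max); the restart
with the lowest objective wins, and a restart whose starting objective
is non-finite is redrawn. BFGS with finite-difference gradients often
terminates with a "precision loss" status at a perfectly good optimum,
so a restart also counts as converged when its final gradient norm is
below 1e-3. Two numerical guards keep the objective finite far from the
optimum: exp(u) is capped at exp(50) and the logistic output is kept
inside the open unit interval; both bind only in regions no fit settles
in. Degenerate sessions (e.g., a subject always pressing one key) leave
some directions of the posterior nearly flat; the prior keeps the
optimum finite, and such fits are returned with a warning rather than an
error.

The one-step EM variant sets the new prior mean to the sample mean of
the unbounded MAP estimates across all sessions (two sessions per
subject treated as independent) and the new prior variance to their
sample variance plus, by default, the mean per-fit Laplace variance
(inverse of the diagonal numerical curvature of the negative log
posterior at the mode, curvature floored at 1e-2 so flat directions give
large but finite variances), floored at 1e-4; the Laplace inflation is a
standard empirical-Bayes approximation and can be switched off. Exactly
one EM iteration is performed, after which every session is refit under
the new prior.

## Synthetic cohorts

The generator emulates the study design: n subjects (default 33), two
within-subject conditions with counterbalanced order, a Gaussian
working-memory covariate (mean 7.39, SD 1.78, matching a backwards
Digit Span distribution; integer rounding optional), and subject-level
unbounded parameters drawn Normal(population mean, between-subject SD).
The population defaults (means 0.4, 0.7, 1.3, 1.1, 0.9, 1.2, 0.75;
SDs 1.0, 0.6, 1.0, 0.4, 0.5, 0.6, 0.5 on the unbounded scale) were
chosen once so the implied natural-scale medians (α₁ ≈ 0.60, α₂ ≈ 0.67,
λ ≈ 0.79, β₂ ≈ 3.0, β_HB ≈ 2.5, β_GD ≈ 3.3, p ≈ 0.75) fall inside
interquartile ranges typical of healthy adults on this task.

The gaming condition shifts each subject's unbounded β_GD by
`effect_beta_gd_condition + effect_beta_gd_interaction · z_wm`. The
defaults (−0.17, +0.24) encode the qualitative pattern of interest — a
simple gaming effect of −0.41 one SD below mean working memory and ≈ 0
one SD above — and setting both to zero gives an exact null generator.
An optional `session_sd` adds independent session-to-session Gaussian
variability to all unbounded parameters, emulating test–retest
variability of the latent parameters themselves; it defaults to 0 so
that, under the null, a subject's two sessions share identical
parameters.

What the generator does **not** emulate: missing trials and response
lapses, integer/bounded covariate artifacts (unless rounding is turned
on), correlations between parameters and covariates (working memory is
independent of baseline parameters by construction), order/practice
effects, and any structural change of the decision process between
conditions (effects are purely parametric shifts). Passing recovery and
calibration tests therefore shows the chain is correct and well
calibrated under the assumed generative family, not that real data meet
those assumptions.

## Group statistics

Models are linear mixed-effects regressions with random subject
intercepts fitted by REML (statsmodels `MixedLM`; optimizer falls back
through lbfgs → bfgs → powell → nm because the profiled REML objective
can be numerically singular at the zero-variance boundary). In the
balanced two-observations-per-subject case the condition coefficient
equals the paired mean difference exactly, which the tests use as an
oracle. Degrees of freedom are residual: n_obs − k_fixed −
(n_subjects − 1); for the paired design this reproduces the classic
paired-t df of n − 1. No Satterthwaite approximation is attempted, and
df conventions that mix within- and between-subject information are
explicitly out of scope.

The moderator is z-scored across subjects (sample SD) inside the model
function, making coefficients standardized and scale-invariant; simple
effects re-center the z-scored moderator at ±1 SD and read off the
condition coefficient, so simple(+1) − simple(−1) = 2 × interaction
holds identically (verified to 1e-6). One-tailed p-values use the t
distribution on the residual df; the directed hypotheses are coded as
music = 0, gaming = 1, H₁: condition coefficient < 0 for β_GD and
H₁: interaction > 0. Bonferroni correction is min(1, m·p) with m = 6 for
the exploratory parameter family.

The stay-probability diagnostic tabulates P(repeat first-stage choice)
by previous reward × previous transition type; empty cells are reported
as NaN. Simulated pure-habitual agents show a main effect of reward and
simulated pure-goal-directed agents a reward × transition interaction,
which is the behavioral signature used in the property tests.

## Problem sizes and calibration checks

Parameter recovery is measured at 100 simulated subjects × 201 trials
(study scale; unbounded β_GD and β_HB recover with r ≥ 0.5) and at
2,000 trials (asymptotic check; r ≥ 0.9). λ is the least identifiable
parameter at study scale and no recovery threshold is claimed for it.

Type-I calibration of the one-tailed interaction test uses 200 replicate
null cohorts of 16 subjects drawn with session-level parameter
variability (session_sd 0.4) and no condition effects, testing the
generator-level parameters directly; this isolates the calibration of
the inference layer and keeps the replicate count high. Effect recovery
then exercises the full simulate → fit → test chain once at full study
size (33 subjects, 201 trials, 6 restarts) under a strong injected
deficit (condition −0.5, interaction +0.5), checking the qualitative
pattern: significant negative simple effect at −1 SD working memory,
null at +1 SD.

## Reproducibility

All randomness descends from a master seed through SHA-256 derivation
(`derive_seed(master, *tags)` → 31-bit child seed), one stream per
schedule, simulation, fit, replicate and stage; results are therefore
independent of execution order and of whether fits run in parallel
(joblib, off by default).

## Known limitations

* The transition matrix is assumed known to the agent; learned-structure
  variants and model comparison are out of scope.
* MAP under a near-flat prior can produce extreme unbounded estimates
  for weakly identified sessions (visible as heavy tails on the natural
  scale); the EM prior shrinks these but is itself a one-step
  approximation, not a full hierarchical fit.
* Mixed-model df are one documented convention among several; exact
  replication of df values produced by other software is not promised.
* The walk SD and initialization are conventions; analyses that depend
  sensitively on the reward-schedule autocorrelation should treat them
  as free design choices.
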