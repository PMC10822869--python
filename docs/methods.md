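# Methods

## Model and assumptions

The package models trial-level correctness in a dynamic
facial-emotion-recognition task as a Bernoulli GLM with a logit link.
The linear predictor combines three condition-indexed effects:

* an intercept `α` per (group × feedback × emotion) cell — 24 slots —
  interpreted as the log-odds of a correct response when both covariate
  terms vanish, i.e. at full intensity (RT = 10 s) on the tenth
  presentation of that emotion in its block;
* an intensity penalty `β_RT ≥ 0` multiplying `ln(RT/10)`.  The log
  transform encodes two assumptions: recognition at 0% intensity is
  impossible other than by chance (the covariate diverges to −∞), and
  marginal penalties shrink as intensity grows (1 s vs 2 s matters more
  than 9 s vs 10 s).  The sign constraint encodes that a fuller
  expression is never harder to recognise.
* a learning term `β_Trial` multiplying `((10 − Trial)/9)^e`, equal to 1
  on the first presentation and 0 on the tenth, so `β_Trial` is directly
  the first-vs-last-trial log-odds difference.  The exponent `e` front-
  loads learning toward the earliest trials.

The slope parameters share 18 slots over (3 feedback conditions ×
6 emotions): both groups use one slot in the no-feedback block, because
group membership is defined by the feedback they will receive and
cannot influence behaviour before feedback differs.

Schizotypy enters for SPQ completers only, through standardized CP /
IN / DI factor scores: additive per-SD direct effects and proportional
moderation of `β_RT` and `β_Trial` (`β → β·(1 + Σ b_k z_k)`).  The
moderation factor can in principle make an effective slope negative
for extreme scores; the constraint binds the base `β_RT` only, and the
tight N(0, 0.1) moderation priors make sign flips rare.  Completers
and non-completers share one joint likelihood (common `α`, `β_RT`,
`β_Trial`); setting all z-scores to zero reduces the extended
predictor exactly to the base model.  There are no participant-level
random effects, no RT likelihood, and no modelling of which wrong
label was chosen.

Priors (second argument an SD): `α ~ N(0, 1.5)`,
`β_RT ~ Half-N(0, 1)`, `β_Trial ~ N(0, 1)`, direct `~ N(0, 0.25)`,
moderation `~ N(0, 0.1)`.  222 free parameters in total.

## Inference and decision rules

Posterior contrasts are computed draw-wise (subtraction per saved
draw), summarized by the mean and a 95% highest-density interval, and
judged against regions of practical equivalence:

| quantity | ROPE | derivation |
|---|---|---|
| accuracy contrasts (percent) | ±5.0 points | half of the 10% per-participant sensitivity of a 10-trial condition |
| `β_RT` contrasts | {0} | any intensity-penalty difference matters, as the penalty diverges at low RT |
| `β_Trial` and its contrasts | ±0.2 | `logit(0.55) ≈ 0.2007`: the log-odds change moving 50% accuracy by 5 points |
| SPQ direct effects (per SD) | ±0.1 | the 0.2 bound spread over a 2-SD predictor span |
| SPQ moderation | ±0.005 | a 1% proportional change in the moderated effect over a 2-SD span |

A contrast is *credible* when the HDI completely excludes the ROPE
(strictly — a shared endpoint blocks the verdict), *negligible* when
the HDI lies entirely inside it, and *withheld* otherwise.  The HDI is
the deterministic sorted-window search (shortest window holding
⌈0.95·n⌉ sorted draws, leftmost on ties), cross-checked in the tests
against an exhaustive window scan and arviz.  Every emitted table
decision is reproducible from its own interval and ROPE; credibility
is an explicit boolean column, never formatting.

Sign conventions (configurable via `ContrastConvention`): accuracy
contrasts are Feedback − NoFeedback and DOP − NOP; RT-penalty group
contrasts are DOP − NOP; learning-curve feedback contrasts are
NoFeedback-first.  Intercepts are reported as percent accuracy,
`100·logit⁻¹(α)`.

## Sampling

The posterior is sampled by Hamiltonian Monte Carlo implemented in
this package with fully analytic gradients:

* dual-averaging step-size adaptation toward a 0.8 acceptance rate;
* a diagonal mass matrix re-estimated in expanding, memoryless warmup
  windows (25, 50, 100, … iterations after a 75-iteration settling
  buffer, with a 50-iteration terminal step-size buffer), each
  estimate shrunk toward a small constant when windows are short;
* trajectory length ≈ 1.2 time units, leapfrog count jittered over the
  upper half of its range, capped at 48 steps;
* the `β_RT ≥ 0` constraint handled by **boundary reflection**:
  position and momentum bounce off zero, which is exact for a
  half-space and keeps the sampler on the scale where the half-normal
  density is finite and well conditioned.

A log-transform parameterization with the exact Jacobian is also
implemented (`model.make_posterior_fn`) and verified by the gradient
check, but it is not used for production sampling: the half-normal's
boundary mass maps to an infinitely long flat tail in log space, and
chains that wandered down that tail during warmup inflated the mass
estimates and collapsed the step size at full design size.  Reflection
showed none of that pathology (all split-R̂ near 1, coverage and
recovery criteria met), so it is the default; the choice affects the
sampler only, never the posterior being sampled.

Defaults mirror the study budget: 4 chains × 2500 saved draws after
1000 warmup (10,000 saved).  Chains initialize from prior draws shrunk
by 0.5, with bounded re-initialization if the log posterior is not
finite.  Convergence is summarized by the plain split-chain
Gelman-Rubin statistic computed here (identical chains give 1; the
tests verify agreement with arviz to 1e-10), with a rank-normalized
variant available via `gelman_rubin(..., method="rank")`.  An adaptive
random-walk Metropolis fallback (`algorithm="rwm"`) exists for
gradient-free cross-checks only; it mixes far too slowly for the full
model.

Numerical choices: probabilities are clipped to `[1e-12, 1 − 1e-12]`
inside the likelihood only, so rounding alone never yields −∞;
trajectories whose energy error exceeds 1000 are counted as divergent
and rejected; covariate transforms raise domain errors outside
(0, 10] s or trial 1–10.

## Synthetic data

`synthgen` generates datasets with the task's design and the model's
exact statistical structure, so parameter recovery can exercise every
stage without any download.  Defaults are the study conditions: 88 DOP
and 95 NOP participants; two blocks (no-feedback then feedback) of
6 emotions × 10 actors in seeded random order; 58 + 51 SPQ completers
drawn uniformly within group.  Correctness comes from the model's own
linear predictor at known true parameters.

What is deliberately fixture machinery:

* **RTs** are truncated-lognormal per (feedback, emotion) — medians
  3–6 s, log-SD 0.45, inverse-CDF sampling on (0, 10] — because the
  model treats RT as an observed covariate and makes no claim about
  its law.  Real RTs need not be lognormal, independent of
  correctness, or block-stationary.
* **SPQ scores** are drawn as correlated trivariate normal z-scores
  (pairwise r = 0.45 by default); raw scores are back-filled by a
  rank-preserving affine map anchored at the study sample's factor
  means/SDs and clipped into 0–33/0–33/0–16, with a feasible
  Suspiciousness share keeping the 0–74 total consistent.  Only the
  z-scores enter the model, so the back-fill affects no inference.

Consequently, passing recovery tests shows the inference machinery is
correct and calibrated *under the model's own assumptions*; it cannot
show that real recognition behaviour follows the model (no lapses, no
RT-accuracy dependence beyond the penalty term, no label-confusion
structure).

True-parameter presets: `null` (all zeros — chance performance
everywhere), `paper-like` (intercepts and slopes at the magnitudes of
the study's posterior means, with one extreme near-ceiling cell capped
at logit 5.0 to stay within the prior's plausible range; small SPQ
effects, since none were credible), and `strong-moderation`
(paper-like base effects with large direct ±0.2 and moderation ±0.08
coefficients, for power exploration).

## SPQ scoring

The 74 dichotomous items map onto nine subscales with the standard
published sizes (Ideas of Reference 9, Suspiciousness 8, Odd Beliefs
7, Unusual Perceptual Experiences 9, Social Anxiety 8, No Close
Friends 9, Constricted Affect 8, Odd Behaviour 7, Odd Speech 9) —
the only allocation consistent with factor ranges 0–33 / 0–33 / 0–16
and a 0–74 total.  (Descriptions of the instrument sometimes state
seven items per subscale; that is arithmetically incompatible with
those ranges and is not used.)  Suspiciousness belongs to both CP and
IN but counts once toward the total.  The default item→subscale map
lays subscales out contiguously and is configurable for questionnaires
with a specific published item order; factor-level inputs bypass it
entirely.  Reliability is Cronbach's alpha over each factor's item
set; standardization uses the completer subsample's mean and
population SD (divisor n, configurable).

## Problem sizes used in the tests

Desk-scale checks run in milliseconds.  The simulation-based checks
use: full-design recovery (183 participants, 21,960 trials, 109
completers) with 4 chains × 500 saved after 500 warmup; null
calibration over 20 datasets of 20 participants × 2 emotions with 2 ×
150 draws; prior recovery with 4 × 600 draws; a quadrature comparison
on an 80-trial intercept-only cell.  These sizes give Monte-Carlo
error well inside every tolerance asserted.

## Known limitations

* No participant random effects: repeated trials are conditionally
  independent given condition, which understates between-person
  heterogeneity present in real data.
* The HMC implementation is static-trajectory (no dynamic termination
  criterion); heavily correlated posteriors may need a longer
  `trajectory_length`.
* `spq_effect_summary` requires a fit that actually saw SPQ data;
  prior-only schizotypy estimates are refused rather than reported.
* The generator does not simulate the six-way label choice, timed-out
  trials, or emotion-confusion structure.
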