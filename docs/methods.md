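# Methods

`psmsim` is a Monte Carlo laboratory for studying propensity-score matching
(PSM) with replacement and oversampling when samples are small — the regime
typical of observational surgical cohorts, where 1:1 matching without
replacement can discard much of an already small study. It follows the ADEMP
structure (aims, data-generating mechanisms, estimands, methods, performance
measures). This note records the models, the parameters that matter, the
numerical choices, and the places where the design was genuinely open.

## Data-generating mechanism

Each simulated cohort has six baseline covariates drawn from a latent
multivariate normal with zero means and unit variances. The correlation
matrix is Toeplitz with lag-*k* correlation `0.6 − 0.1k` (off-diagonals
0.5, 0.4, 0.3, 0.2, 0.1 — spanning a weak-to-moderate dependence range);
positive definiteness is asserted at construction. The first three latent
variables are binarized at the standard-normal quantiles giving marginal
probabilities 0.25, 0.30 and 0.20 (a latent value exactly at the cutoff
codes as 0; a probability-zero event fixed for determinism).

Treatment is Bernoulli with

    logit P(T=1 | x) = β0 + βᵀx,

where β is `log(1.25, 1.5, 1.25, 1.5, 1.25, 1.5)` ("weak" assignment) or
`log(1.5, 1.75, 1.5, 1.75, 1.5, 1.75)` ("strong"). The intercept β0 is
calibrated so the marginal treated proportion is 0.3, 0.5 or 0.7.

The primary outcome family is logistic:

    logit P(Y=1 | x, T) = γ0 + γᵀx + γ_T·T,

with γ = `log(1.25, 1.25, 1.5, 1.5, 1.75, 1.75)` (weak through strong
confounding). γ_T is calibrated so that the average treatment effect on the
treated (ATT), on the absolute risk-difference scale, is 0.15; γ0 so that
the marginal outcome prevalence is 0.20. The risk difference is collapsible,
so the ATT equals the mean of the subject-level counterfactual differences
`p1 − p0` among the treated; the logit link makes those subject-level
differences heterogeneous.

The secondary family is a linear probability model, `p0 = clip(γ0 + γᵀx,
0, 1)`, `p1 = clip(p0 + γ_T, 0, 1)` with γ_T = 0.15, which removes the
effect heterogeneity. Its covariate coefficients are set to
`(0.005, 0.005, 0.01, 0.01, 0.015, 0.015)` on the risk-difference scale —
the same 1:1:2:2:3:3 pattern as the logistic γ, scaled so that probability
clamping stays a sub-percent event in every scenario (with marginal
prevalence 0.20, ATT 0.15 and up to 70% treated, the baseline risk must
average ≈0.095, so larger coefficients would push a visible fraction of
subjects below zero). Calibration fails loudly if the clamping fraction
reaches 1%; the achieved worst case is ≈0.03%.

### Calibration

The three calibrated quantities are each monotone in their parameter, so the
"grid search" is refined into bracketed root finding (Brent's method) on a
dedicated calibration draw of 10⁶ subjects with a fixed, documented seed:
β0 on the mean assignment probability; then, for the logistic family, an
inner γ_T loop (ATT among the treated) and an outer γ0 loop (marginal
prevalence of the observed outcome, treatment effect included) iterated to
joint convergence, at most 20 outer iterations. The contract tolerance is
5×10⁻³ on each probability; internally the loop is run to residuals ≲2×10⁻⁴
so the achieved values sit mid-band. The achieved oracle ATT — the
large-sample mean of `p1 − p0` among the treated, not the nominal 0.15 — is
stored on the scenario and used as the truth by all performance measures.
Whether prevalence is calibrated before or after adding the treatment effect
is not externally fixed; it is defined here as the marginal prevalence of
the observed outcome (treatment included).

Calibrated coefficients depend only on (family, assignment strength, treated
proportion), so each of the 6 combinations per family is calibrated once and
shared across the four sample sizes (100, 250, 500, 1000); they can be
exported to and reloaded from a CSV table.

## Propensity model and matching

The propensity score is estimated per cohort by maximum-likelihood logistic
regression of treatment on all six covariates as main effects (statsmodels).
Non-convergence and perfect separation are flagged, and the affected
replication is marked invalid rather than dropped silently.

Matching is greedy nearest-neighbour on the **logit** propensity score with
a caliper of 0.2 sample standard deviations (ddof=1) of the logit PS over
the full cohort. Ten strategies are crossed per cohort: with/without
replacement × ratio K = 1..5. Design choices:

* Treated units are processed in a seeded random permutation (the greedy
  order is not externally specified; randomizing avoids systematic order
  artifacts and is reproducible). With replacement the result is
  order-independent, which is exploited to build all five ratios from one
  candidate pass.
* Distance is the absolute difference on the logit-PS scale — the same
  scale as the caliper.
* Exact distance ties are broken by the lower control index (deterministic
  and testable).
* Within a matched set of m controls, the treated unit carries weight 1 and
  each control weight 1/m — the reciprocal-reuse convention of ratio
  matching.
* **Partial sets.** Two policies are implemented for a treated unit with
  fewer than K admissible (in-caliper, available) controls. The strict
  policy discards it entirely; the partial policy keeps the controls it
  found and discards only zero-candidate treated units. `match()` defaults
  to strict; the simulation engine and the applied-analysis command use the
  partial policy, which mirrors reference matching software in which the
  caliper drops matched *pairs* rather than whole treated units. Under the
  strict policy the estimand drifts with K whenever treated units are hard
  to match (at 70% treated the discarded units carry the largest individual
  effects, inflating apparent bias several-fold); under the partial policy
  the matched population is stable across K. The proportion of matched
  treated (PMT) counts only treated units that received the full
  prespecified K, so it decreases with K under either policy.

## Balance diagnostics

Standardized mean differences divide the (weighted) treated-minus-control
mean by the pooled SD `sqrt((s_t² + s_c²)/2)` computed on the *unmatched*
cohort, with `p(1−p)` variances for binary covariates — so pre- and
post-matching SMDs share a denominator. The ASMD averages absolute SMDs
(signed averaging would let imbalances cancel). The overlap coefficient
(OVL) integrates the pointwise minimum of weighted Gaussian kernel density
estimates of the propensity score (probability scale) in the two matched
groups: Silverman bandwidth, 512-point grid over the pooled range padded by
three bandwidths, trapezoidal integration; a 10⁻³ bandwidth floor covers
degenerate single-valued groups. 1−OVL is reported alongside ASMD. On
matched samples all diagnostics use the aggregate matching weights
(unmatched units carry zero weight).

## ATT estimation and variances

The ATT is estimated as the mean over matched sets of
`y_treated − mean(y_controls)` — the weighted absolute risk reduction under
the 1/m convention. Two standard errors:

* **Standard** (matched-set paired-difference): `sd(d_i)/√n_sets` with
  sample SD over the set-level differences. For 1:1 binary data this is the
  classical matched-pairs variance (verified against the 2×2 discordance
  table in tests). The original description cites references that are not
  reproduced here; this paired-difference form is the documented
  interpretation.
* **Abadie–Imbens** (replacement only):
  `V = n⁻²[Σᵢ(dᵢ − τ̂)² + Σⱼ(Kⱼ² − K′ⱼ)σ̂²ⱼ]`, where for control j,
  `Kⱼ = Σ 1/mᵢ` and `K′ⱼ = Σ 1/mᵢ²` over the sets containing j, and
  `σ̂²ⱼ = (yⱼ − y_ℓ(j))²/2` with ℓ(j) the nearest *other control* on the
  logit-PS scale (single-neighbour conditional variance, ties to the lower
  index). The correction is nonnegative and vanishes exactly when no
  control is reused at ratio 1.

Confidence intervals are normal-theory `τ̂ ± z·SE` at 95%; no t
correction (a documented knob, justified by the replication framing).

## Simulation engine

The full study is {weak, strong} × {0.3, 0.5, 0.7} × {100, 250, 500, 1000}
= 24 scenarios per outcome family × 10 strategies, default 10,000
replications per scenario (overridable for desk-scale runs). Each
replication draws one cohort, fits one propensity model shared by all ten
strategies (common random numbers across strategies), and emits one tidy
record per strategy. Seeding is hierarchical — study seed → scenario code →
replication index (→ strategy for processing order) via `SeedSequence` — so
any single replication is reproducible in isolation and results are
independent of the number of parallel workers. Invalid replications
(propensity non-convergence, degenerate caliper, fewer than two matched
sets) are excluded from summaries and counted.

Performance per cell: relative bias `|mean(τ̂) − ATT_true|/ATT_true × 100`;
RMSE `sqrt(Var(τ̂) + bias²)` with population-denominator variance over valid
replications (fixed for determinism; negligible versus R−1 at study scale);
nominal coverage of each CI method against the scenario's oracle ATT; mean
ASMD, 1−OVL, PMT and PRC (proportion of distinct matched controls used
more than once — identically 0 without replacement).

## What the generator does and does not emulate

The synthetic cohorts reproduce the statistical skeleton of small
observational surgery cohorts: correlated mixed binary/continuous
confounders, moderate treatment-assignment signal, a rare-ish binary
outcome (20%), and a clinically meaningful risk difference (0.15).
They do **not** emulate measurement error, missing data, unmeasured
confounding, covariate–treatment interactions in the assignment model,
time-to-event structure, or the heavy-tailed covariates of real registries
— so passing tests demonstrate correctness of the estimators and the
internal consistency of the study design, not robustness of PSM on any
particular real dataset.

## Problem sizes used by the test suite and acceptance script

Calibration draws use 10⁶ subjects. The headline bias check runs the 12
logistic scenarios with n ∈ {500, 1000} at 500 replications per cell for
the five with-replacement strategies; directional checks at n=100 use 500
replications of all ten strategies. These sizes give Monte Carlo standard
errors of roughly 1–2 percentage points on relative bias and ±0.01 on
coverage, adequate for the directional and bounded claims being checked.

## Known limitations

* The correlation matrix and the linear-family coefficients are this
  package's explicit choices within stated ranges; other choices satisfying
  the same ranges would shift the bias/coverage surfaces quantitatively.
* With the partial-set policy, relative bias with replacement is nearly
  flat in K at n=100 rather than increasing; the increase reappears under
  the strict-discard policy (at the cost of large incomplete-matching bias
  at high treated proportions) and under a pair-weight (m/K) convention.
  The flat profile is the behaviour of the implemented convention, not a
  bug; see the matching section.
* The Abadie–Imbens variant uses a single same-group neighbour for the
  conditional variances and no finite-sample adjustment.
* Bootstrap variances and propensity-estimation uncertainty are out of
  scope by design.
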