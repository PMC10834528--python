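# Methods

## Estimand and the one-model transformation

The package targets the individual treatment effect on a binary success
probability in a two-arm randomized trial,
`uplift(x) = P_T(Y=1|x) − P_C(Y=1|x)`. It uses the one-model
(class-variable transformation) approach: relabel `Z = 1` for treated
successes and control failures, `Z = 0` otherwise, and fit one probabilistic
classifier for `Z`. Under two assumptions — allocation independent of the
covariates, and equal allocation probability for both arms — the identity
`uplift(x) = 2·P(Z=1|x) − 1` holds. Both assumptions are properties of a 1:1
randomized trial, and the synthetic generator enforces them (blocked
allocation, |n_T − n_C| ≤ 1). When arms are imbalanced the identity is
biased: the score's *scale* degrades while the *ranking* usually survives.
Classifier probabilities are used raw — no calibration — for the same
reason: the downstream Qini machinery is rank-based, so miscalibration
distorts the reported score values and the nominal cutoff but not the
ordering of subjects.

## Qini conventions

Given scores, arms, and successes, subjects are ranked by descending score
and the incremental-success curve
`Qini(φ) = S_T(φ) − S_C(φ)·N_T(φ)/N_C(φ)` is evaluated against rank. Choices
that the formula alone does not determine, all pinned here and covered by
tests:

- **Ties** are processed as blocks; the curve is evaluated only at block
  boundaries, making it invariant to subject order within a tie.
- **All-treated prefix** (`N_C = 0`): the control correction is undefined;
  the curve equals `S_T`, its limit, and exported curves flag these rows.
- **Diagonal**: the chord from (0, 0) to (n, full-depth curve value) — the
  expected incremental success under random targeting.
- **Coefficient**: signed trapezoidal area between curve and diagonal over
  rank, reported unnormalized; a normalized variant (area/n) exists for
  cross-cohort comparison. Absolute coefficient values are therefore not
  comparable across differently sized cohorts, and are not meaningful
  reproduction targets in themselves — only the argmax over candidates is
  used.
- **Cutoff**: the score at the rank maximizing curve − diagonal, ties toward
  the smaller rank (the stricter cutoff). One could read the defining
  sentence of the cutoff with the opposite sign (diagonal − curve); that
  reading would select the *worst* separation and contradicts the stated
  purpose, so the maximizing convention is used. If the maximum excess is
  ≤ 0 the run is flagged "no benefit", the cutoff is +inf, and every test
  subject falls in the low stratum — reported as a warning, never an error.
- **Model selection**: argmax of the validation Qini coefficient,
  deterministic tie-break by candidate order.

## Pipeline and leakage discipline

Splits follow registration (enrollment) order and are purely positional:
outer (training, test), inner (model-training, validation). Split sizes are
explicit parameters because two successive "1:1" splits of an odd cohort
can round either way; the convenience default is (ceil, floor) and the
workflow-shape preset pins (249, 248) and (124, 125) for a 497-subject
cohort. The preprocessing recipe (missingness screen at 0.15, mean /
"not available" imputation, correlation pruning at 0.7, median/IQR scaling
with type-7 quantiles) is fitted on the model-training part only and applied
as a frozen, pure function everywhere else; whether the original analysis
computed these statistics before or after splitting is unknowable from the
outside, so the leakage-safe order is enforced by construction. The test
set is first read only after the selected model and cutoff are frozen; a
test perturbs the test half of a cohort and verifies that recipe, selection
and cutoff are bit-identical.

Correlation pruning refuses to run without an explicit keep-priority list
when a correlated group exists: "most informative" is clinical judgement,
not a computable rule. Pearson r is used on imputed continuous pairs only;
categorical features are never pruned (r is undefined for unordered levels).

## Survival analysis choices

Within each stratum, arms are compared by intention to treat: Kaplan–Meier
product-limit curves, the log-rank test, and an unadjusted Cox model whose
treatment coefficient gives the HR with Wald 95% CI and p. Both the Cox
Wald p and the log-rank p are always reported, labelled, because clinical
reports mix the two. Ties use Efron's method. Effect modification is the
Wald p of the product term in a Cox model with treatment, stratum, and
treatment×stratum over the whole test set; it requires all four
arm-by-stratum cells non-empty and is otherwise skipped with a warning.
Proportional hazards are checked with the scaled-Schoenfeld
correlation-with-time test (rank transform) at the 0.05 level. Monotone
likelihood (complete separation) is flagged, not fatal. A consistency
property worth noting: duplicating every subject leaves the Cox estimate
essentially unchanged (only up to Efron's tie correction, since duplication
creates exact ties) while narrowing the CI.

Desk statistics: the two-sided Fisher exact test uses the
probability-summation definition (the convention matching standard
statistical software on published 2×2 tables). The Mann–Whitney U test uses
an exact null distribution for combined n ≤ 20 — computed by dynamic
programming over midrank sums, which handles ties exactly and gives p = 1
for identical samples — and the tie-corrected normal approximation with
continuity correction otherwise.

## The synthetic-trial generator

The generator emulates a persistent-AF ablation trial: defaults of n = 500
subjects, 1:1 blocked allocation, ~26 mixed baseline covariates whose
marginals follow the trial population (median age 66, ~25% female, ~61%
smokers, log-normal BNP/CRP/creatinine, echo measurements), a control-arm
one-year success probability of ~0.72, administrative censoring at 12
months, and MCAR missingness on a handful of labs, including one echo
feature at 20% so the default scenario exercises the missingness screen.

Success probabilities are logistic: `p_C = expit(η)` with
`η = baseline_logit + Σ nuisance_j·u_j` over standardized covariates, and
`p_T = expit(η + Δ)` with
`Δ = benefit_scale·(benefit_intercept + Σ benefit_j·u_j)`. The true uplift
`p_T − p_C` is thus bounded and valid without renormalization
(benefit_scale = 0 gives exactly zero uplift everywhere). Default benefit
coefficients plant the profile the method should find — female sex (+), no
smoking history (−), lower hemoglobin (−), lower BNP (−), larger left
atrium (+), no sleep apnea (−) — and `benefit_intercept = 0.7` was
calibrated once, against the generator alone, so the arm-level success gap
(~8.6 points) matches the source trial's observed recurrence gap (22.6% vs
31.5%); the induced subgroup effect is strong (top-half true uplift ~+0.2,
bottom-half ~−0.05).

Event times are a stand-in, since the source reports no per-subject time
distribution: failures recur uniformly on (0, 12] months and successes are
censored at 12. An alternative constant-hazard mode inverts the per-subject
hazard to hit the same one-year failure probability and supports
proportional-hazards parameter-recovery tests. Missingness is MCAR only.
Consequently, passing tests demonstrate correctness of the machinery and
recoverability of a planted signal under clean conditions; they do not
demonstrate robustness to informative censoring, informative missingness,
time-varying effects, or covariate joint structure beyond marginals — none
of which the generator produces.

## Experiment sizes and thresholds

The replicated experiments use 50 synthetic trials of n = 2000 (outer split
1000/1000, inner 500/500) with a fast two-candidate set (logistic
regression, adaptive boosting) — sizes chosen so each replicate completes
in about a second while the test set still yields stable stratum HRs.
Recovery is declared when the high stratum's HR is below the low stratum's
in ≥ 80% of replicates with median high-stratum HR < 1; null calibration
(benefit_scale = 0) requires Kolmogorov–Smirnov uniformity of the
interaction p at a loose threshold and a Schoenfeld pass rate in
[0.85, 1.0], the binomial range around the nominal 95% for 50 replicates.
These bands were fixed before the experiments were first run.

## Known limitations

- Absolute Qini coefficients are cohort-size dependent (unnormalized by
  default) and are not comparable across studies.
- The 2P(Z=1)−1 identity is exact only under balanced allocation; mild
  imbalance within registration-order splits is tolerated but biases the
  score scale.
- Classifier hyperparameters are the registry's documented defaults (plus a
  small covariance regularizer for quadratic discriminant analysis, which
  is otherwise ill-posed on one-hot designs); no tuning loop is provided.
- At trial-realistic sizes (~120 training subjects) model selection and
  cutoff choice are noisy; single-split results at that scale should be
  read as workflow demonstrations, not stable effect estimates.
- No covariate-adjusted Cox models, competing risks, bootstrap CIs for Qini
  quantities, or cross-validated pipelines.
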