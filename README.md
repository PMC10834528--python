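# uplift-rct

Who actually benefits from the intensified arm of a randomized trial?

`uplift-rct` implements a complete, tested pipeline for answering that
question in a two-arm RCT with a binary success endpoint and a parallel
time-to-event endpoint — the setting of ablation trials in persistent atrial
fibrillation, where extensive ablation added to pulmonary vein isolation
(PVI-plus) helps some patients and not others. The package estimates a
per-subject **uplift score**, selects among candidate models with the **Qini
coefficient**, fixes a score **cutoff**, and validates the resulting strata
on an untouched test set with survival analysis. Because real trial data of
this kind are rarely public, a seeded synthetic-trial generator with planted,
covariate-dependent benefit provides ground truth for every stage.

## The method

For covariates $X$, arm $T \in \{\text{treatment}, \text{control}\}$ and
success $Y \in \{0, 1\}$, the estimand is the individual treatment effect on
the success probability

$$\mathrm{uplift}(x) = P_T(Y=1 \mid X=x) - P_C(Y=1 \mid X=x).$$

With 1:1 randomization independent of $X$, the **class-variable
transformation** $Z = 1$ for treated successes and control failures (else 0)
turns this into a single binary classification problem:

$$P_T(Y=1\mid X) - P_C(Y=1\mid X) = 2\,P(Z=1 \mid X) - 1,$$

so any probabilistic classifier for $Z$ yields an uplift score in $[-1, 1]$.
Candidate classifiers (logistic regression, discriminant analysis, naive
Bayes, k-NN, trees and boosting ensembles — a pluggable registry) are
compared on a validation split by the **Qini curve**: ranking subjects by
descending score and writing $S_T(\varphi), S_C(\varphi), N_T(\varphi),
N_C(\varphi)$ for cumulative successes and counts per arm at score
$\ge \varphi$,

$$\mathrm{Qini}(\varphi) = S_T(\varphi) - S_C(\varphi)\,\frac{N_T(\varphi)}{N_C(\varphi)},$$

plotted against rank. The Qini coefficient is the area between this curve
and the random-targeting diagonal; the model with the largest coefficient
wins, and the optimal cutoff $\varphi^*$ is the score at the rank maximizing
curve-minus-diagonal. The test set — never touched before this point — is
stratified at $\varphi^*$ (closed on the high side) and the arms are compared
within each stratum by Kaplan–Meier curves, log-rank tests, unadjusted Cox
hazard ratios with Wald 95% CIs (Efron ties), a treatment-by-stratum Cox
interaction test, and a scaled-Schoenfeld proportional-hazards check.
Baseline tables use clinical conventions: `median [Q1, Q3]` with Mann–Whitney
U (exact null distribution for combined n ≤ 20), `n (%)` with two-sided
Fisher exact tests.

Preprocessing is fitted on the training split only: features missing in
>15% of subjects are dropped; continuous missing values take the training
mean and categorical ones a constant `"not available"` level; continuous
features with pairwise |r| > 0.7 are pruned to one per group via an explicit
priority list; survivors are centered at the median and scaled by the IQR.

## Worked example

```python
from uplift_rct import PipelineConfig, default_trial_config, run_pipeline

cfg = PipelineConfig(
    synthetic=default_trial_config(n=2000, seed=0),
    classifier_ids=("logistic_regression", "adaptive_boosting"),
    seed=0,
)
print(run_pipeline(cfg).summary())
```

```
Uplift trial analysis
=====================
cohort n=2000; splits outer=(1000, 1000), inner=(500, 500)
kept features (20): age, body_mass_index, hemoglobin, bnp, creatinine, crp, ...

Model selection (validation Qini coefficient):
  logistic_regression              Q=3189.067  cutoff=0.1804 <- selected
  adaptive_boosting                Q=2411.374  cutoff=-0.0616

Selected: logistic_regression; uplift-score cutoff = 0.1804

Test stratum 'high' (score >= cutoff): n=280
  treatment: 20/137 events (14.6%)
  control:   54/143 events (37.8%)
  HR 0.35 (95% CI 0.21-0.58); Cox p=0.000; log-rank p=0.000
Test stratum 'low' (score < cutoff): n=720
  treatment: 97/374 events (25.9%)
  control:   97/346 events (28.0%)
  HR 0.90 (95% CI 0.68-1.19); Cox p=0.444; log-rank p=0.443
Treatment-by-stratum interaction p = 0.002
Schoenfeld proportional-hazards check: pass (treated=0.927)
```

Reading this: the generator planted a treatment benefit concentrated in a
covariate-defined subgroup. On held-out data the Qini-selected cutoff
isolates a high-uplift stratum in which the treated arm has far fewer
recurrences (HR 0.35) while the low-uplift stratum shows no significant arm
difference (HR 0.90), and the interaction test confirms the effect
modification — exactly the pattern the method is designed to recover.
At trial-realistic sizes (`paper_shape_config()`: n=497 split 249/248 then
124/125) the same workflow runs end-to-end but stratum estimates are
noisy, as expected with ~120 training subjects.

A CLI wraps the same machinery:

```bash
uplift-rct simulate --n 500 --seed 1 --out runs/sim
uplift-rct run --config cfg.yaml
uplift-rct qini --scores scores.csv --cohort cohort.csv --schema schema.json
```

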