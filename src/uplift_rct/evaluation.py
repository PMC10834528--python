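"""Cutoff-stratified outcome analysis for the held-out test set.

Subjects are split at the chosen uplift-score cutoff (closed on the high side:
score >= phi* is "high"). Within each stratum the randomized arms are compared
by intention to treat: Kaplan-Meier curves, a log-rank test, and an unadjusted
Cox proportional-hazards model (Efron tie handling) giving the treatment
hazard ratio with Wald 95% CI and p-value. Effect modification is tested with
a Cox model over the whole test set containing treatment, stratum, and their
product, reporting the Wald p of the interaction term. The proportional-
hazards assumption is checked with the scaled-Schoenfeld residual test.

Baseline-characteristics machinery follows clinical-table conventions:
continuous rows as ``median [Q1, Q3]`` with a Mann-Whitney U p-value
(exact null distribution for combined n <= 20, normal approximation with tie
correction otherwise), binary rows as ``n (%)`` with a two-sided Fisher exact
p (probability-summation definition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test

from .cohort import ARM_CONTROL, ARM_TREATMENT, CohortTable

STRATUM_HIGH = "high"
STRATUM_LOW = "low"


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify_by_cutoff(scores, cutoff: float) -> np.ndarray:
    """Label each subject 'high' (score >= cutoff) or 'low' (score < cutoff)."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores >= cutoff, STRATUM_HIGH, STRATUM_LOW).astype(object)


# ---------------------------------------------------------------------------
# desk statistics
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (probability summation)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if t.sum() <= 0:
        raise ValueError("table must have a positive grand total")
    return float(stats.fisher_exact(np.round(t).astype(int), alternative="two-sided").pvalue)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits.

    Uses a dynamic program over the distribution of the rank sum of the first
    sample (midranks doubled to integers, so ties are handled exactly). The
    two-sided p is P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|) under the uniform
    null over all C(n, n1) splits.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2 * stats.rankdata(pooled, method="average")).astype(int)
    r1_obs = int(ranks2[:n1].sum())

    total = int(ranks2.sum())
    # dp[k][s] = number of k-subsets of the doubled midranks summing to s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n1 - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if len(nz):
                dp[k + 1, nz + r] += row[nz]
    counts = dp[n1]

    # doubled identities: 2U = 2R1 - n1(n1+1), E[2U] = n1 n2; r1_obs and sums
    # below are already doubled rank sums
    mu2u = n1 * n2
    base = n1 * (n1 + 1)
    dev_obs = abs((r1_obs - base) - mu2u)
    sums = np.arange(total + 1)
    dev = np.abs((sums - base) - mu2u)
    p = counts[dev >= dev_obs - 1e-9].sum() / comb(n1 + n2, n1)
    return float(min(1.0, p))


def mann_whitney_u(x, y, exact_limit: int = 20) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration (tie-aware) when the combined sample size is at most
    ``exact_limit``; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if len(x) + len(y) <= exact_limit:
        return _exact_mwu_p(x, y)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a step function (time, survival).

    Censored subjects leave the risk set without creating a step.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times <= 0).any():
        raise ValueError("event times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_p(times, events, arm) -> float:
    """Two-group log-rank test p-value (treatment vs control)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    arm = np.asarray(arm, dtype=object)
    t_mask = arm == ARM_TREATMENT
    res = _ll_logrank(times[t_mask], times[~t_mask], events[t_mask], events[~t_mask])
    return float(res.p_value)


def _cox_frame(times, events, arm) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=int),
            "treated": (np.asarray(arm, dtype=object) == ARM_TREATMENT).astype(int),
        }
    )


def cox_treatment_hr(times, events, arm) -> dict:
    """Unadjusted treatment HR with Wald 95% CI and p (Efron ties).

    Returns ``{'hr', 'ci_low', 'ci_high', 'p', 'flagged'}``; ``flagged`` marks
    convergence trouble (e.g. monotone likelihood under complete separation).
    """
    df = _cox_frame(times, events, arm)
    if df["treated"].nunique() < 2:
        raise ValueError("both arms must be present")
    if df["event"].sum() < 1:
        raise ValueError("at least one event is required")
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
        flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    row = cph.summary.loc["treated"]
    return {
        "hr": float(np.exp(row["coef"])),
        "ci_low": float(np.exp(row["coef lower 95%"])),
        "ci_high": float(np.exp(row["coef upper 95%"])),
        "p": float(row["p"]),
        "flagged": flagged,
        "_fitter": cph,
        "_frame": df,
    }


@dataclass
class InteractionResult:
    """Wald test of treatment-by-stratum effect modification in a Cox model."""

    interaction_p: float
    coef_treatment: float
    coef_stratum: float
    coef_interaction: float


def cox_interaction(times, events, arm, stratum) -> InteractionResult:
    """Cox model with treatment, stratum (high=1), and their product term."""
    df = _cox_frame(times, events, arm)
    df["high"] = (np.asarray(stratum, dtype=object) == STRATUM_HIGH).astype(int)
    cells = df.groupby(["treated", "high"]).size()
    if len(cells) < 4:
        raise ValueError("all four arm-by-stratum cells must be non-empty")
    df["treated_x_high"] = df["treated"] * df["high"]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    return InteractionResult(
        interaction_p=float(s.loc["treated_x_high", "p"]),
        coef_treatment=float(s.loc["treated", "coef"]),
        coef_stratum=float(s.loc["high", "coef"]),
        coef_interaction=float(s.loc["treated_x_high", "coef"]),
    )


def schoenfeld_check(cox_result: dict, alpha: float = 0.05) -> dict:
    """Scaled-Schoenfeld proportional-hazards test for a fitted treatment model.

    Takes the dict returned by :func:`cox_treatment_hr`; returns per-term
    p-values and a pass flag at ``alpha`` (pass = no evidence against
    proportional hazards).
    """
    df = cox_result["_frame"]
    if df["event"].sum() < 2:
        raise ValueError("at least two events are required for the Schoenfeld check")
    res = proportional_hazard_test(cox_result["_fitter"], df, time_transform="rank")
    ps = {str(ix): float(res.summary.loc[ix, "p"]) for ix in res.summary.index}
    return {"p": ps, "pass": all(p > alpha for p in ps.values())}


# ---------------------------------------------------------------------------
# stratum comparison
# ---------------------------------------------------------------------------

@dataclass
class StratumComparison:
    """Arm-vs-arm outcome summary within one uplift-score stratum."""

    stratum: str
    n_treatment: int
    n_control: int
    events_treatment: int
    events_control: int
    km_treatment: pd.DataFrame | None
    km_control: pd.DataFrame | None
    logrank_p: float | None
    hazard_ratio: float | None
    ci95: tuple[float, float] | None
    cox_p: float | None
    flagged: bool = False
    warning: str | None = None

    @property
    def event_fraction_treatment(self) -> float:
        return self.events_treatment / self.n_treatment if self.n_treatment else float("nan")

    @property
    def event_fraction_control(self) -> float:
        return self.events_control / self.n_control if self.n_control else float("nan")


def compare_stratum(times, events, arm, stratum_label: str) -> StratumComparison:
    """Full arm comparison inside one stratum; degrades to counts when degenerate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    arm = np.asarray(arm, dtype=object)
    t_mask = arm == ARM_TREATMENT
    n_t, n_c = int(t_mask.sum()), int((~t_mask).sum())
    e_t, e_c = int(events[t_mask].sum()), int(events[~t_mask].sum())
    base = dict(stratum=stratum_label, n_treatment=n_t, n_control=n_c,
                events_treatment=e_t, events_control=e_c)
    if n_t == 0 or n_c == 0:
        return StratumComparison(**base, km_treatment=None, km_control=None, logrank_p=None,
                                 hazard_ratio=None, ci95=None, cox_p=None,
                                 warning=f"stratum {stratum_label!r} has an empty arm")
    km_t = km_estimate(times[t_mask], events[t_mask])
    km_c = km_estimate(times[~t_mask], events[~t_mask])
    if e_t + e_c == 0:
        return StratumComparison(**base, km_treatment=km_t, km_control=km_c, logrank_p=None,
                                 hazard_ratio=None, ci95=None, cox_p=None,
                                 warning=f"stratum {stratum_label!r} has no events")
    lr = logrank_p(times, events, arm)
    cox = cox_treatment_hr(times, events, arm)
    return StratumComparison(**base, km_treatment=km_t, km_control=km_c, logrank_p=lr,
                             hazard_ratio=cox["hr"], ci95=(cox["ci_low"], cox["ci_high"]),
                             cox_p=cox["p"], flagged=cox["flagged"])


# ---------------------------------------------------------------------------
# characteristics tables
# ---------------------------------------------------------------------------

def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna().astype(str)))
    return vals <= {"0", "1", "0.0", "1.0"}


def _fmt_median_iqr(x: pd.Series) -> str:
    x = x.dropna().astype(float)
    if len(x) == 0:
        return "NA"
    return f"{x.median():.2f} [{x.quantile(0.25):.2f}, {x.quantile(0.75):.2f}]"


def _fmt_count_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f})" if n else "0 (NA)"


def characteristics_table(cohort: CohortTable, grouping, features: list[str] | None = None) -> pd.DataFrame:
    """Clinical-style characteristics table across a two-group partition.

    Continuous features render ``median [Q1, Q3]`` per group with a
    Mann-Whitney p; binary features render ``n (%)`` (count of positive level)
    with a Fisher exact p. Multi-level categorical features render counts per
    level without a p-value. Missing values are excluded row-wise.
    """
    grouping = np.asarray(grouping, dtype=object)
    if len(grouping) != cohort.n:
        raise ValueError("grouping must label every subject")
    groups = list(pd.unique(grouping))
    if features is None:
        features = list(cohort.schema.features)
    rows = []
    df = cohort.data
    for f in features:
        col = df[f]
        if f in cohort.schema.continuous:
            cells = {g: _fmt_median_iqr(col[grouping == g]) for g in groups}
            p = np.nan
            if len(groups) == 2:
                a = col[grouping == groups[0]].dropna().to_numpy(dtype=float)
                b = col[grouping == groups[1]].dropna().to_numpy(dtype=float)
                if len(a) and len(b):
                    p = 1.0 if (np.ptp(np.concatenate([a, b])) == 0) else mann_whitney_u(a, b)
            rows.append({"feature": f, **cells, "p": p})
        elif _is_binary(col):
            pos = col.astype(str).isin(["1", "1.0"])
            obs = col.notna()
            cells, counts = {}, []
            for g in groups:
                m = (grouping == g) & obs
                k, n = int((pos & m).sum()), int(m.sum())
                cells[g] = _fmt_count_pct(k, n)
                counts.append((k, n - k))
            p = fisher_exact_2x2(np.array(counts)) if len(groups) == 2 else np.nan
            rows.append({"feature": f, **cells, "p": p})
        else:
            levels = sorted(col.dropna().astype(str).unique())
            for lev in levels:
                cells = {}
                for g in groups:
                    m = (grouping == g) & col.notna()
                    k = int((col.astype(str)[m] == lev).sum())
                    cells[g] = _fmt_count_pct(k, int(m.sum()))
                rows.append({"feature": f"{f}={lev}", **cells, "p": np.nan})
    return pd.DataFrame(rows).set_index("feature")
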