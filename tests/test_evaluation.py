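import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uplift_rct import (
    characteristics_table,
    cox_interaction,
    cox_treatment_hr,
    fisher_exact_2x2,
    km_estimate,
    mann_whitney_u,
    schoenfeld_check,
    stratify_by_cutoff,
)
from uplift_rct.evaluation import logrank_p

from conftest import make_cohort


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_stratification_is_closed_at_the_cutoff():
    strata = stratify_by_cutoff([0.0124, 0.0123, 0.5, -1.0], 0.0124)
    assert list(strata) == ["high", "low", "high", "low"]


def test_all_below_cutoff_gives_empty_high_stratum():
    strata = stratify_by_cutoff([-0.5, -0.1], 0.0)
    assert (strata == "low").all()


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------

def test_fisher_identical_rows_p_is_one():
    assert fisher_exact_2x2([[5, 10], [5, 10]]) == pytest.approx(1.0)


def test_fisher_invariant_to_transposition_and_row_swap():
    t = np.array([[26, 38], [10, 42]])
    p = fisher_exact_2x2(t)
    assert fisher_exact_2x2(t.T) == pytest.approx(p)
    assert fisher_exact_2x2(t[::-1]) == pytest.approx(p)
    assert fisher_exact_2x2(t[:, ::-1]) == pytest.approx(p)


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mwu_identical_multisets_give_p_one():
    assert mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)


def test_mwu_exact_matches_brute_force_enumeration():
    x, y = [1.0, 2.0], [10.0, 20.0]
    # brute force: every C(4,2) assignment of the pooled values to the x slots
    pooled = x + y
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(1 for a in x for b in y if a == b)
    mu = len(x) * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(4), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(4) if i not in idx]
        u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(1 for a in xs for b in ys if a == b)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    assert mann_whitney_u(x, y) == pytest.approx(count / total)
    assert mann_whitney_u(x, y) == pytest.approx(1 / 3)


def test_mwu_exact_handles_ties_correctly():
    x, y = [1.0, 2.0, 2.0], [2.0, 3.0]
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(1 for a in xs for b in ys if a == b)

    u_obs = u_stat(x, y)
    mu = len(x) * len(y) / 2
    hits = total = 0
    for idx in itertools.combinations(range(5), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(5) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    assert mann_whitney_u(x, y) == pytest.approx(hits / total)


def test_mwu_null_p_values_are_roughly_uniform_at_large_n():
    rng = np.random.default_rng(5)
    ps = [mann_whitney_u(rng.normal(size=30), rng.normal(size=30)) for _ in range(300)]
    assert stats.kstest(ps, "uniform").pvalue > 0.001


def test_mwu_rejects_empty_sample():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_events_is_flat_one():
    km = km_estimate([3.0, 6.0, 12.0], [0, 0, 0])
    assert (km["survival"] == 1.0).all()


def test_km_three_distinct_events_steps_by_thirds():
    km = km_estimate([2.0, 5.0, 9.0], [1, 1, 1])
    steps = km.set_index("time")["survival"]
    assert steps[2.0] == pytest.approx(2 / 3)
    assert steps[5.0] == pytest.approx(1 / 3)
    assert steps[9.0] == pytest.approx(0.0)


def test_km_matches_hand_product_limit_with_censoring():
    # 6 subjects: events at 2 and 6; censored at 3, 6, 8; event at 10
    times = [2.0, 3.0, 6.0, 6.0, 8.0, 10.0]
    events = [1, 0, 1, 0, 0, 1]
    km = km_estimate(times, events).set_index("time")["survival"]
    # risk sets: t=2 ->6, t=6 ->4, t=10 ->1
    assert km[2.0] == pytest.approx(5 / 6)
    assert km[6.0] == pytest.approx(5 / 6 * 3 / 4)
    assert km[10.0] == pytest.approx(5 / 6 * 3 / 4 * 0)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(11)
    times = rng.uniform(0.5, 11.5, size=50)
    km = km_estimate(times, np.ones(50, dtype=int))
    for t, s in zip(km["time"], km["survival"]):
        assert s == pytest.approx((times > t).mean())


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _exp_two_arm(n, hr, seed, horizon=12.0, lam_c=0.03):
    rng = np.random.default_rng(seed)
    arm = np.array(["treatment", "control"] * (n // 2), dtype=object)
    lam = np.where(arm == "treatment", lam_c * hr, lam_c)
    t = rng.exponential(1 / lam)
    events = (t <= horizon).astype(int)
    times = np.minimum(t, horizon)
    return times, events, arm


def test_cox_recovers_true_hazard_ratio():
    times, events, arm = _exp_two_arm(5000, hr=2.0, seed=3)
    res = cox_treatment_hr(times, events, arm)
    assert 1.8 <= res["hr"] <= 2.2
    assert res["ci_low"] < res["hr"] < res["ci_high"]


def test_cox_null_hr_near_one_with_ci_covering_one():
    times, events, arm = _exp_two_arm(4000, hr=1.0, seed=4)
    res = cox_treatment_hr(times, events, arm)
    assert res["ci_low"] < 1.0 < res["ci_high"]
    assert 0.8 < res["hr"] < 1.25


def test_cox_duplicated_data_keeps_estimate_and_narrows_ci():
    times, events, arm = _exp_two_arm(600, hr=1.6, seed=5)
    res1 = cox_treatment_hr(times, events, arm)
    res2 = cox_treatment_hr(np.tile(times, 2), np.tile(events, 2), np.tile(arm, 2))
    # duplication creates exact ties, so Efron handling shifts the estimate slightly
    assert res2["hr"] == pytest.approx(res1["hr"], rel=1e-2)
    assert (res2["ci_high"] - res2["ci_low"]) < (res1["ci_high"] - res1["ci_low"])


def test_cox_requires_events_and_both_arms():
    with pytest.raises(ValueError, match="event"):
        cox_treatment_hr([12.0, 12.0], [0, 0], ["treatment", "control"])
    with pytest.raises(ValueError, match="arms"):
        cox_treatment_hr([5.0, 6.0], [1, 1], ["treatment", "treatment"])


def test_logrank_agrees_with_cox_direction():
    times, events, arm = _exp_two_arm(2000, hr=2.0, seed=6)
    assert logrank_p(times, events, arm) < 0.01


# ---------------------------------------------------------------------------
# interaction & Schoenfeld
# ---------------------------------------------------------------------------

def test_interaction_detects_planted_heterogeneity_with_correct_sign():
    rng = np.random.default_rng(7)
    n = 4000
    arm = np.array(["treatment", "control"] * (n // 2), dtype=object)
    stratum = np.array((["high"] * 2 + ["low"] * 2) * (n // 4), dtype=object)
    lam = np.full(n, 0.03)
    benefit = (arm == "treatment") & (stratum == "high")  # treatment helps only the high stratum
    lam[benefit] *= 0.4
    t = rng.exponential(1 / lam)
    events = (t <= 12).astype(int)
    times = np.minimum(t, 12)
    res = cox_interaction(times, events, arm, stratum)
    assert res.interaction_p < 0.01
    # high coded 1: benefit concentrated there makes the product coefficient negative
    assert res.coef_interaction < 0


def test_interaction_requires_all_four_cells():
    with pytest.raises(ValueError, match="cell"):
        cox_interaction([1.0, 2.0, 3.0], [1, 1, 1],
                        ["treatment", "control", "treatment"], ["high", "high", "low"])


def test_schoenfeld_passes_under_proportional_hazards():
    times, events, arm = _exp_two_arm(2000, hr=1.5, seed=8)
    res = cox_treatment_hr(times, events, arm)
    check = schoenfeld_check(res)
    assert set(check["p"]) == {"treated"}
    assert check["p"]["treated"] > 0.05


def test_schoenfeld_rejects_crossing_hazards():
    # treated hazard rises over time (Weibull shape 3), control hazard falls
    # (shape 0.5): the relative hazard crosses, grossly violating PH
    rng = np.random.default_rng(9)
    n = 2000
    arm = np.array(["treatment", "control"] * (n // 2), dtype=object)
    t = np.where(arm == "treatment", 6 * rng.weibull(3.0, n), 5 * rng.weibull(0.5, n))
    t = np.clip(t, 1e-3, None)
    events = (t <= 12).astype(int)
    res = cox_treatment_hr(np.minimum(t, 12), events, arm)
    assert schoenfeld_check(res)["p"]["treated"] < 0.05


def test_schoenfeld_needs_at_least_two_events():
    res = cox_treatment_hr([5.0, 12.0, 12.0, 12.0], [1, 0, 0, 0],
                           ["treatment", "control", "treatment", "control"])
    with pytest.raises(ValueError, match="two events"):
        schoenfeld_check(res)


# ---------------------------------------------------------------------------
# characteristics tables
# ---------------------------------------------------------------------------

def test_characteristics_constant_feature_has_p_one():
    cohort = make_cohort(["treatment", "control"] * 10, [1, 0] * 10,
                         features={"lab": [4.2] * 20})
    tab = characteristics_table(cohort, cohort.data["arm"].to_numpy())
    assert tab.loc["lab", "p"] == pytest.approx(1.0)
    assert tab.loc["lab", "treatment"] == "4.20 [4.20, 4.20]"


def test_characteristics_percentages_render_from_counts():
    # a 52-subject group with 10 positives renders "10 (19.2)"
    flags = [1] * 10 + [0] * 42 + [1] * 26 + [0] * 38
    groups = ["g1"] * 52 + ["g2"] * 64
    n = len(flags)
    cohort = make_cohort(["treatment", "control"] * (n // 2), [1, 0] * (n // 2),
                         features={"recurrence": [str(f) for f in flags]})
    tab = characteristics_table(cohort, np.array(groups, dtype=object))
    assert tab.loc["recurrence", "g1"] == "10 (19.2)"
    assert tab.loc["recurrence", "g2"] == "26 (40.6)"
    expected = fisher_exact_2x2([[10, 42], [26, 38]])
    assert tab.loc["recurrence", "p"] == pytest.approx(expected)


def test_characteristics_continuous_row_uses_mann_whitney():
    rng = np.random.default_rng(13)
    vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
    cohort = make_cohort(["treatment", "control"] * 30, [1, 0] * 30,
                         features={"lab": vals})
    grouping = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
    tab = characteristics_table(cohort, grouping)
    assert tab.loc["lab", "p"] < 0.001
    assert "[" in tab.loc["lab", "a"]
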