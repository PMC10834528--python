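import itertools

import numpy as np
import pytest

from uplift_rct import (
    QiniSummary,
    build_summary,
    compute_qini_curve,
    qini_coefficient,
    select_best_model,
    select_optimal_cutoff,
)


# ---------------------------------------------------------------------------
# independent hand oracle: evaluate the cumulative formula threshold by
# threshold, then integrate curve-minus-diagonal with explicit trapezoids
# ---------------------------------------------------------------------------

def oracle_curve(scores, arms, successes):
    n = len(scores)
    points = []
    for phi in sorted(set(scores), reverse=True):
        idx = [i for i in range(n) if scores[i] >= phi]
        n_t = sum(1 for i in idx if arms[i] == "treatment")
        n_c = len(idx) - n_t
        s_t = sum(successes[i] for i in idx if arms[i] == "treatment")
        s_c = sum(successes[i] for i in idx if arms[i] == "control")
        q = float(s_t) if n_c == 0 else s_t - s_c * n_t / n_c
        points.append([len(idx), phi, s_t, s_c, n_t, n_c, q])
    final = points[-1][6]
    return [p + [p[0] / n * final] for p in points]


def oracle_coefficient(points):
    xs = [0.0] + [p[0] for p in points]
    ds = [0.0] + [p[6] - p[7] for p in points]
    area = 0.0
    for i in range(len(xs) - 1):
        area += 0.5 * (ds[i] + ds[i + 1]) * (xs[i + 1] - xs[i])
    return area


def test_six_subject_worked_example():
    # descending scores, arms (T,C,T,C,T,C), successes (1,0,0,1,1,0)
    scores = [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
    arms = ["treatment", "control"] * 3
    succ = [1, 0, 0, 1, 1, 0]
    pts = compute_qini_curve(scores, arms, succ)
    by_rank = {p.rank: p for p in pts}
    p2 = by_rank[2]
    assert (p2.s_t, p2.s_c, p2.n_t, p2.n_c) == (1, 0, 1, 1)
    assert p2.qini_value == pytest.approx(1.0)
    p6 = by_rank[6]
    assert (p6.s_t, p6.s_c, p6.n_t, p6.n_c) == (2, 1, 3, 3)
    assert p6.qini_value == pytest.approx(1.0)
    # area agrees with the independent trapezoid oracle
    assert qini_coefficient(pts) == pytest.approx(oracle_coefficient(oracle_curve(scores, arms, succ)))


def test_full_depth_value_is_ordering_free():
    rng = np.random.default_rng(0)
    arms = list(rng.choice(["treatment", "control"], size=30, p=[0.5, 0.5]))
    if "treatment" not in arms:
        arms[0] = "treatment"
    if "control" not in arms:
        arms[1] = "control"
    succ = list(rng.integers(0, 2, size=30))
    expected_end = None
    for _ in range(3):
        scores = rng.normal(size=30)
        pts = compute_qini_curve(scores, arms, succ)
        end = pts[-1].qini_value
        if expected_end is None:
            s_t = sum(s for s, a in zip(succ, arms) if a == "treatment")
            s_c = sum(s for s, a in zip(succ, arms) if a == "control")
            n_t = arms.count("treatment")
            n_c = arms.count("control")
            expected_end = s_t - s_c * n_t / n_c
        assert end == pytest.approx(expected_end)


def test_no_control_successes_gives_cumulative_treated_successes():
    scores = [5.0, 4.0, 3.0, 2.0]
    arms = ["treatment", "control", "treatment", "control"]
    succ = [1, 0, 1, 0]
    pts = compute_qini_curve(scores, arms, succ)
    assert [p.qini_value for p in pts] == [1.0, 1.0, 2.0, 2.0]


def test_exhaustive_oracle_equivalence_small_cohorts():
    """Curve and coefficient match the hand oracle on every arm/success
    configuration for n = 2..6 with distinct descending scores."""
    for n in range(2, 7):
        scores = [1.0 - i / n for i in range(n)]
        for arms in itertools.product(["treatment", "control"], repeat=n):
            if "treatment" not in arms or "control" not in arms:
                continue
            for succ in itertools.product([0, 1], repeat=n):
                pts = compute_qini_curve(scores, list(arms), list(succ))
                exp = oracle_curve(scores, list(arms), list(succ))
                assert len(pts) == len(exp)
                for p, e in zip(pts, exp):
                    assert (p.rank, p.threshold_phi, p.s_t, p.s_c, p.n_t, p.n_c) == tuple(e[:6])
                    assert p.qini_value == pytest.approx(e[6], abs=1e-12)
                    assert p.diagonal_value == pytest.approx(e[7], abs=1e-12)
                assert qini_coefficient(pts) == pytest.approx(oracle_coefficient(exp), abs=1e-12)


def test_curve_invariant_to_monotone_transform_and_tie_order():
    rng = np.random.default_rng(3)
    n = 40
    arms = ["treatment", "control"] * (n // 2)
    succ = list(rng.integers(0, 2, size=n))
    scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties

    base = build_summary(scores, arms, succ)
    mono = build_summary(np.exp(3 * scores), arms, succ)  # strictly increasing map
    assert [p.qini_value for p in mono.points] == [p.qini_value for p in base.points]
    assert mono.qini_coefficient == pytest.approx(base.qini_coefficient)
    assert mono.no_benefit == base.no_benefit

    # permuting subjects within tie blocks cannot change the curve
    perm = rng.permutation(n)
    permuted = build_summary(scores[perm], [arms[i] for i in perm], [succ[i] for i in perm])
    assert [p.qini_value for p in permuted.points] == [p.qini_value for p in base.points]
    assert permuted.optimal_cutoff == base.optimal_cutoff


def test_randomly_permuted_scores_average_to_zero_coefficient():
    rng = np.random.default_rng(9)
    n = 200
    arms = ["treatment", "control"] * (n // 2)
    succ = list(rng.integers(0, 2, size=n))
    coefs = []
    for _ in range(200):
        scores = rng.permutation(n).astype(float)
        coefs.append(qini_coefficient(compute_qini_curve(scores, arms, succ)))
    coefs = np.array(coefs)
    se = coefs.std() / np.sqrt(len(coefs))
    assert abs(coefs.mean()) < 4 * se + 1e-9


def test_cutoff_at_unique_maximum_and_degenerate_flag():
    scores = [0.9, 0.5, 0.1, -0.2]
    arms = ["treatment", "control", "control", "treatment"]
    succ = [1, 0, 1, 0]
    pts = compute_qini_curve(scores, arms, succ)
    diffs = [p.qini_value - p.diagonal_value for p in pts]
    phi, flag = select_optimal_cutoff(pts)
    assert not flag
    assert phi == pts[int(np.argmax(diffs))].threshold_phi

    # anti-ranked scores: curve dips below a flat diagonal and never exceeds it
    bad = compute_qini_curve([0.9, 0.6, 0.4, 0.2],
                             ["control", "treatment", "control", "treatment"],
                             [1, 0, 0, 1])
    assert all(p.qini_value - p.diagonal_value <= 0 for p in bad)
    phi2, flag2 = select_optimal_cutoff(bad)
    assert flag2 and phi2 == float("inf")


def test_model_selection_argmax_and_errors():
    mk = lambda cid, q: QiniSummary(points=[], qini_coefficient=q, optimal_cutoff=0.0,
                                    no_benefit=False, classifier_id=cid)
    assert select_best_model([mk("only", 0.2)]) == "only"
    assert select_best_model([mk("a", 0.4), mk("b", 0.1)]) == "a"
    assert select_best_model([mk("a", 0.4), mk("b", 0.4)]) == "a"  # tie -> list order
    with pytest.raises(ValueError):
        select_best_model([])


def test_oracle_scorer_beats_random_scorer():
    from uplift_rct import default_trial_config, generate_cohort

    cohort, truth = generate_cohort(default_trial_config(n=3000, seed=31))
    arms = cohort.data["arm"].to_numpy()
    succ = cohort.data["success"].to_numpy()
    rng = np.random.default_rng(1)
    oracle = qini_coefficient(compute_qini_curve(truth["true_uplift"].to_numpy(), arms, succ))
    random_coefs = [
        qini_coefficient(compute_qini_curve(rng.normal(size=len(arms)), arms, succ))
        for _ in range(20)
    ]
    assert oracle > np.mean(random_coefs)
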