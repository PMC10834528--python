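"""Qini curves, Qini coefficients, model selection and cutoff choice.

Subjects are ranked by descending uplift score. With S_T(phi), S_C(phi) the
cumulative successes and N_T(phi), N_C(phi) the cumulative subject counts in
each arm among scores >= phi, the incremental-success curve is

    Qini(phi) = S_T(phi) - S_C(phi) * N_T(phi) / N_C(phi),

plotted against rank (not against the score itself). The diagonal is the chord
from (0, 0) to (n, Qini at full depth): the incremental success expected if
treatment targeting were random. The Qini coefficient is the signed area
between curve and diagonal (trapezoidal, over rank); the optimal cutoff phi*
is the score at the rank maximizing curve - diagonal.

Conventions pinned here:

* tied scores are processed as one block, so the curve is evaluated only at
  block boundaries and is invariant to subject order within ties;
* while no control subject has entered (N_C = 0) the control correction is
  undefined and the curve equals S_T (the formula's limit), flagged in exports;
* cutoff ties break toward the smaller rank (the stricter cutoff); when the
  curve never rises above the diagonal the cutoff is flagged "no benefit" and
  set to +inf (every subject falls in the low stratum);
* the coefficient is reported unnormalized (raw area on the rank axis); a
  normalized variant (area / n) is available for cross-cohort comparison.

All quantities are rank-based: any strictly increasing transform of the scores
leaves curve, coefficient and cutoff unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ARM_CONTROL, ARM_TREATMENT


@dataclass(frozen=True)
class QiniPoint:
    rank: int            # 1-based position in descending-score order (block end)
    threshold_phi: float  # uplift score at this rank
    s_t: int
    s_c: int
    n_t: int
    n_c: int
    qini_value: float
    diagonal_value: float


@dataclass
class QiniSummary:
    points: list[QiniPoint]
    qini_coefficient: float
    optimal_cutoff: float
    no_benefit: bool
    classifier_id: str | None = None


def compute_qini_curve(scores, arms, successes) -> list[QiniPoint]:
    """Qini curve points at every tie-block boundary, descending-score order."""
    scores = np.asarray(scores, dtype=float)
    arms = np.asarray(arms, dtype=object)
    successes = np.asarray(successes, dtype=int)
    if not (len(scores) == len(arms) == len(successes)):
        raise ValueError("scores, arms and successes must be aligned")
    n = len(scores)
    if n == 0:
        raise ValueError("empty cohort")
    treated = arms == ARM_TREATMENT
    control = arms == ARM_CONTROL
    if not treated.any() or not control.any():
        raise ValueError("both arms must be present to compute a Qini curve")

    order = np.argsort(-scores, kind="stable")
    s, t, y = scores[order], treated[order], successes[order]

    points: list[QiniPoint] = []
    n_t = n_c = s_t = s_c = 0
    i = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # tie block
            j += 1
        blk_t = t[i:j]
        blk_y = y[i:j]
        n_t += int(blk_t.sum())
        n_c += int((~blk_t).sum())
        s_t += int(blk_y[blk_t].sum())
        s_c += int(blk_y[~blk_t].sum())
        if n_c == 0:
            q = float(s_t)  # control correction undefined on the all-treated prefix
        else:
            q = s_t - s_c * n_t / n_c
        points.append(QiniPoint(rank=j, threshold_phi=float(s[i]), s_t=s_t, s_c=s_c,
                                n_t=n_t, n_c=n_c, qini_value=q, diagonal_value=np.nan))
        i = j

    final = points[-1].qini_value
    points = [
        QiniPoint(p.rank, p.threshold_phi, p.s_t, p.s_c, p.n_t, p.n_c, p.qini_value,
                  diagonal_value=(p.rank / n) * final)
        for p in points
    ]
    return points


def qini_coefficient(points: list[QiniPoint], normalized: bool = False) -> float:
    """Signed trapezoidal area between curve and diagonal over rank (from rank 0)."""
    if not points:
        raise ValueError("empty curve")
    ranks = np.concatenate([[0.0], [p.rank for p in points]])
    diffs = np.concatenate([[0.0], [p.qini_value - p.diagonal_value for p in points]])
    area = float(np.trapezoid(diffs, ranks))
    if normalized:
        area /= points[-1].rank
    return area


def select_optimal_cutoff(points: list[QiniPoint]) -> tuple[float, bool]:
    """(phi*, no_benefit): score at the rank maximizing curve - diagonal.

    Ties break toward the smaller rank. If the maximum excess is <= 0 the
    cutoff is flagged no-benefit and returned as +inf.
    """
    if not points:
        raise ValueError("empty curve")
    diffs = np.array([p.qini_value - p.diagonal_value for p in points])
    k = int(np.argmax(diffs))  # first occurrence = smaller rank
    if diffs[k] <= 0:
        return float("inf"), True
    return points[k].threshold_phi, False


def build_summary(scores, arms, successes, classifier_id: str | None = None) -> QiniSummary:
    points = compute_qini_curve(scores, arms, successes)
    phi, no_benefit = select_optimal_cutoff(points)
    return QiniSummary(
        points=points,
        qini_coefficient=qini_coefficient(points),
        optimal_cutoff=phi,
        no_benefit=no_benefit,
        classifier_id=classifier_id,
    )


def select_best_model(summaries: list[QiniSummary]) -> str:
    """Classifier id with the highest Qini coefficient; ties break by list order."""
    if not summaries:
        raise ValueError("no candidate summaries")
    best = max(range(len(summaries)), key=lambda i: (summaries[i].qini_coefficient, -i))
    return summaries[best].classifier_id


def curve_frame(summary: QiniSummary) -> pd.DataFrame:
    """Curve as a tidy frame (rank, threshold_phi, s_t, s_c, n_t, n_c, qini_value, diagonal_value)."""
    return pd.DataFrame(
        [
            {
                "rank": p.rank,
                "threshold_phi": p.threshold_phi,
                "s_t": p.s_t,
                "s_c": p.s_c,
                "n_t": p.n_t,
                "n_c": p.n_c,
                "qini_value": p.qini_value,
                "diagonal_value": p.diagonal_value,
                "control_prefix_undefined": p.n_c == 0,
            }
            for p in summary.points
        ]
    )


def plot_qini_curves(summaries: list[QiniSummary], path) -> None:
    """Plot all candidate curves plus the diagonal of the first one."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for summ in summaries:
        ranks = [0] + [p.rank for p in summ.points]
        values = [0.0] + [p.qini_value for p in summ.points]
        ax.plot(ranks, values, label=f"{summ.classifier_id} (Q={summ.qini_coefficient:.2f})")
    ref = summaries[0].points
    ax.plot([0, ref[-1].rank], [0, ref[-1].qini_value], "k--", label="random allocation")
    ax.set_xlabel("rank of uplift score (descending)")
    ax.set_ylabel("cumulative incremental success")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
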