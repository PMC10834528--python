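"""Feature preparation fitted on training data, applied to held-out data.

Four rules, in order:

1. *Missingness screen*: drop any feature missing in strictly more than a
   threshold fraction of training subjects (default 0.15).
2. *Imputation*: continuous missing values take the training mean of the
   observed values; categorical missing values become the constant level
   ``"not available"``, an ordinary level thereafter.
3. *Correlation pruning*: among continuous features with pairwise |Pearson r|
   strictly above a threshold (default 0.7), keep exactly one per correlated
   group — the one ranked highest in an explicit, user-supplied priority list.
   "Most informative" is a judgement call, not a computable rule, so the
   pruner refuses to choose silently.
4. *Robust scaling*: continuous features are centered at the training median
   and scaled by the training interquartile range (linear-interpolation
   quantiles). Zero-IQR features are centered only, with a warning.

All statistics are computed on the training cohort only; applying a recipe is
a pure function of (recipe, input) and never reads statistics from the data it
transforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable

NOT_AVAILABLE = "not available"

MISSINGNESS_THRESHOLD = 0.15
CORRELATION_THRESHOLD = 0.7


class PriorityRequiredError(ValueError):
    """Correlated features were found but no keep-priority was supplied."""


@dataclass
class PreprocessRecipe:
    """A fitted preprocessing recipe, serializable to JSON."""

    kept_continuous: tuple[str, ...]
    kept_categorical: tuple[str, ...]
    missing_threshold: float
    r_threshold: float
    dropped_missingness: dict[str, float]          # feature -> missing fraction
    dropped_correlated: list[tuple[str, str, float]]  # (dropped, kept, r)
    impute_values: dict[str, object]               # continuous -> mean; categorical -> NOT_AVAILABLE
    scale_params: dict[str, tuple[float, float]]   # continuous -> (center, spread); spread 0 => center only

    def __post_init__(self):
        kept = set(self.kept_continuous) | set(self.kept_categorical)
        dropped = set(self.dropped_missingness) | {d for d, _, _ in self.dropped_correlated}
        if kept & dropped:
            raise ValueError(f"features both kept and dropped: {sorted(kept & dropped)}")
        for f in self.kept_continuous:
            if f not in self.impute_values or f not in self.scale_params:
                raise ValueError(f"kept continuous feature {f!r} lacks impute/scale parameters")

    @property
    def kept_features(self) -> tuple[str, ...]:
        return tuple(self.kept_continuous) + tuple(self.kept_categorical)

    def to_json(self, path: str | Path) -> None:
        d = {
            "kept_continuous": list(self.kept_continuous),
            "kept_categorical": list(self.kept_categorical),
            "missing_threshold": self.missing_threshold,
            "r_threshold": self.r_threshold,
            "dropped_missingness": self.dropped_missingness,
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "impute_values": self.impute_values,
            "scale_params": {k: list(v) for k, v in self.scale_params.items()},
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessRecipe":
        d = json.loads(Path(path).read_text())
        return cls(
            kept_continuous=tuple(d["kept_continuous"]),
            kept_categorical=tuple(d["kept_categorical"]),
            missing_threshold=d["missing_threshold"],
            r_threshold=d["r_threshold"],
            dropped_missingness=d["dropped_missingness"],
            dropped_correlated=[tuple(t) for t in d["dropped_correlated"]],
            impute_values=d["impute_values"],
            scale_params={k: tuple(v) for k, v in d["scale_params"].items()},
        )

    def report(self) -> str:
        """Plain-text report of dropped features with reasons."""
        lines = ["Preprocessing report", "====================",
                 f"kept: {', '.join(self.kept_features) or '(none)'}"]
        for f, frac in self.dropped_missingness.items():
            lines.append(f"dropped {f}: missing fraction {frac:.3f} > {self.missing_threshold}")
        for d, k, r in self.dropped_correlated:
            lines.append(f"dropped {d}: |r|={abs(r):.3f} > {self.r_threshold} with kept feature {k}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# individual fitted steps (operate on feature DataFrames)
# ---------------------------------------------------------------------------

def screen_missingness(cohort: CohortTable, threshold: float = MISSINGNESS_THRESHOLD) -> tuple[list[str], dict[str, float]]:
    """Partition features into (kept, dropped{name: fraction}); dropped iff missing fraction > threshold."""
    if cohort.n == 0:
        raise ValueError("empty cohort")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0,1]")
    feats = cohort.features_frame()
    frac = feats.isna().mean()
    kept = [f for f in feats.columns if frac[f] <= threshold]
    dropped = {f: float(frac[f]) for f in feats.columns if frac[f] > threshold}
    return kept, dropped


def fit_impute(df: pd.DataFrame, continuous: list[str], categorical: list[str]) -> dict[str, object]:
    """Training imputation values: mean of observed for continuous, constant level for categorical."""
    values: dict[str, object] = {}
    for f in continuous:
        obs = df[f].dropna()
        if len(obs) == 0:
            raise ValueError(f"continuous feature {f!r} has no observed training values")
        values[f] = float(obs.mean())
    for f in categorical:
        values[f] = NOT_AVAILABLE
    return values


def apply_impute(impute_values: dict[str, object], df: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells from the fitted values; no missing cells remain in covered columns."""
    out = df.copy()
    for f, v in impute_values.items():
        if f in out.columns:
            if out[f].dtype == object:
                out[f] = out[f].where(out[f].notna(), other=v).astype(object)
            else:
                out[f] = out[f].fillna(v)
    return out


def prune_correlated(df: pd.DataFrame, continuous: list[str], r_threshold: float = CORRELATION_THRESHOLD,
                     keep_priority: list[str] | None = None) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Keep one feature per group of |r| > threshold correlated continuous features.

    Groups are connected components of the |r| > threshold graph. Within each
    multi-feature group, the feature appearing earliest in ``keep_priority``
    is kept; the rest are dropped and reported as (dropped, kept, r). Raises
    :class:`PriorityRequiredError` when a correlated group exists but no
    usable priority is given. Categorical features are never pruned (Pearson r
    is undefined for unordered levels).
    """
    if df[continuous].isna().any().any():
        raise ValueError("prune_correlated requires imputed continuous features")
    kept = list(continuous)
    if len(continuous) < 2:
        return kept, []
    corr = df[continuous].corr(method="pearson")
    # connected components of the strict-threshold graph
    adj = {f: set() for f in continuous}
    for i, a in enumerate(continuous):
        for b in continuous[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > r_threshold:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[str] = set()
    dropped: list[tuple[str, str, float]] = []
    drop_set: set[str] = set()
    for f in continuous:
        if f in seen:
            continue
        comp, stack = [], [f]
        while stack:
            g = stack.pop()
            if g in seen:
                continue
            seen.add(g)
            comp.append(g)
            stack.extend(adj[g] - seen)
        if len(comp) == 1:
            continue
        if not keep_priority:
            raise PriorityRequiredError(
                f"correlated features {sorted(comp)} require an explicit keep_priority list"
            )
        ranked = [p for p in keep_priority if p in comp]
        if not ranked:
            raise PriorityRequiredError(
                f"keep_priority covers none of the correlated features {sorted(comp)}"
            )
        keep = ranked[0]
        for g in comp:
            if g != keep:
                dropped.append((g, keep, float(corr.loc[g, keep])))
                drop_set.add(g)
    kept = [f for f in continuous if f not in drop_set]
    return kept, dropped


def fit_scale(df: pd.DataFrame, continuous: list[str]) -> dict[str, tuple[float, float]]:
    """Training (median, IQR) per continuous feature; linear-interpolation quantiles."""
    params: dict[str, tuple[float, float]] = {}
    for f in continuous:
        x = df[f].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"fit_scale requires imputed values ({f!r} has missing cells)")
        center = float(np.quantile(x, 0.5))
        spread = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
        if spread == 0.0:
            warnings.warn(f"feature {f!r} has zero IQR on training data; centered only", UserWarning)
        params[f] = (center, spread)
    return params


def apply_scale(scale_params: dict[str, tuple[float, float]], df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for f, (center, spread) in scale_params.items():
        if f in out.columns:
            if spread == 0.0:
                out[f] = out[f].astype(float) - center
            else:
                out[f] = (out[f].astype(float) - center) / spread
    return out


# ---------------------------------------------------------------------------
# composed recipe
# ---------------------------------------------------------------------------

def fit_recipe(train: CohortTable, missing_threshold: float = MISSINGNESS_THRESHOLD,
               r_threshold: float = CORRELATION_THRESHOLD,
               keep_priority: list[str] | None = None) -> PreprocessRecipe:
    """Fit the full recipe (screen -> impute -> prune -> scale) on a training cohort."""
    kept, dropped_missing = screen_missingness(train, missing_threshold)
    continuous = [f for f in train.schema.continuous if f in kept]
    categorical = [f for f in train.schema.categorical if f in kept]

    feats = train.features_frame()[kept]
    impute_values = fit_impute(feats, continuous, categorical)
    imputed = apply_impute(impute_values, feats)

    kept_cont, dropped_corr = prune_correlated(imputed, continuous, r_threshold, keep_priority)
    scale_params = fit_scale(imputed, kept_cont)

    return PreprocessRecipe(
        kept_continuous=tuple(kept_cont),
        kept_categorical=tuple(categorical),
        missing_threshold=missing_threshold,
        r_threshold=r_threshold,
        dropped_missingness=dropped_missing,
        dropped_correlated=dropped_corr,
        impute_values={f: impute_values[f] for f in list(kept_cont) + categorical},
        scale_params={f: scale_params[f] for f in kept_cont},
    )


def apply_recipe(recipe: PreprocessRecipe, cohort: CohortTable) -> pd.DataFrame:
    """Transform a cohort's features with a fitted recipe (pure function of recipe + input)."""
    missing = [f for f in recipe.kept_features if f not in cohort.data.columns]
    if missing:
        raise ValueError(f"cohort lacks features required by the recipe: {missing}")
    feats = cohort.data[list(recipe.kept_features)].copy()
    feats = apply_impute(recipe.impute_values, feats)
    feats = apply_scale(recipe.scale_params, feats)
    for f in recipe.kept_categorical:
        feats[f] = feats[f].astype(str)
    assert not feats.isna().any().any()
    return feats
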