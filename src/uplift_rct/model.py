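"""End-to-end uplift trial analysis as a Model / Results pair.

:class:`UpliftTrialModel` is built from a cohort and fit() runs the full
workflow on frozen, registration-order splits:

1. outer split -> (training, test); inner split of training -> (model-training,
   validation);
2. preprocessing recipe fitted on the model-training part only;
3. every candidate classifier fitted there on the transformed class variable;
4. Qini curves and coefficients on the validation part; the argmax-coefficient
   candidate is selected and its optimal cutoff frozen;
5. only then is the test set scored, stratified at the cutoff, and analysed:
   per-stratum Kaplan-Meier / log-rank / Cox HR, a treatment-by-stratum
   interaction test, a Schoenfeld proportional-hazards check, and
   characteristics tables.

Test data are never read before step 5; all randomness descends from the
single seed. A degenerate stratum (empty arm or no events) produces an
explicit warning in the results instead of a failure.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, qini
from .classifiers import MANDATORY_CLASSIFIERS, get_spec
from .cohort import CohortSchema, CohortTable
from .evaluation import STRATUM_HIGH, STRATUM_LOW, InteractionResult, StratumComparison
from .preprocess import PreprocessRecipe, fit_recipe
from .simulate import SyntheticConfig, default_trial_config, generate_cohort
from .uplift import UpliftModel, fit_uplift_model, uplift_scores


def _package_version() -> str:
    try:
        return _pkg_version("uplift-rct")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class PipelineConfig:
    """Declarative description of one full pipeline run."""

    synthetic: SyntheticConfig | None = None
    cohort_path: str | None = None
    schema_path: str | None = None
    outer_sizes: tuple[int, int] | None = None
    inner_sizes: tuple[int, int] | None = None
    missing_threshold: float = 0.15
    r_threshold: float = 0.7
    classifier_ids: tuple[str, ...] = MANDATORY_CLASSIFIERS
    keep_priority: tuple[str, ...] | None = None
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.synthetic is None) == (self.cohort_path is None):
            raise ValueError("exactly one of synthetic config or cohort_path is required")
        if not self.classifier_ids:
            raise ValueError("classifier list must be non-empty")
        for cid in self.classifier_ids:
            get_spec(cid)
        for thr in (self.missing_threshold, self.r_threshold):
            if not 0 <= thr <= 1:
                raise ValueError("thresholds must lie in [0,1]")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (str(v) if not isinstance(v, (int, float, str, type(None), list, tuple)) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def paper_shape_config(seed: int = 0, **synthetic_overrides) -> PipelineConfig:
    """Preset reproducing the published workflow shape on synthetic data.

    497 subjects, outer split (249, 248), inner split (124, 125), missingness
    screen at 0.15, correlation pruning at 0.7, and every mandatory classifier
    as a candidate. The 124-subject part trains, the 125-subject part selects
    by Qini, the 248-subject part is the untouched test set.
    """
    return PipelineConfig(
        synthetic=default_trial_config(n=497, seed=seed, **synthetic_overrides),
        outer_sizes=(249, 248),
        inner_sizes=(124, 125),
        classifier_ids=MANDATORY_CLASSIFIERS,
        seed=seed,
    )


class UpliftTrialModel:
    """One-model uplift analysis of a two-arm randomized cohort.

    Parameters
    ----------
    cohort : CohortTable
        The full trial cohort, ordered by registration.
    outer_sizes, inner_sizes : (int, int), optional
        Registration-order split sizes; defaults to (ceil(n/2), floor(n/2))
        at each level.
    classifier_ids : sequence of str
        Candidate classifiers from the registry.
    missing_threshold, r_threshold : float
        Preprocessing thresholds (strict inequalities).
    keep_priority : sequence of str, optional
        Priority list for correlation pruning.
    seed : int
        Drives every classifier fit.
    """

    def __init__(self, cohort: CohortTable, *, outer_sizes=None, inner_sizes=None,
                 classifier_ids=MANDATORY_CLASSIFIERS, missing_threshold: float = 0.15,
                 r_threshold: float = 0.7, keep_priority=None, seed: int = 0):
        if not classifier_ids:
            raise ValueError("classifier list must be non-empty")
        for cid in classifier_ids:
            get_spec(cid)
        self.cohort = cohort
        self.outer_sizes = tuple(outer_sizes) if outer_sizes else None
        self.inner_sizes = tuple(inner_sizes) if inner_sizes else None
        self.classifier_ids = tuple(classifier_ids)
        self.missing_threshold = missing_threshold
        self.r_threshold = r_threshold
        self.keep_priority = list(keep_priority) if keep_priority else None
        self.seed = int(seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: CohortSchema, **kwargs) -> "UpliftTrialModel":
        return cls(CohortTable(df, schema), **kwargs)

    def fit(self) -> "UpliftTrialResults":
        train, test = self.cohort.split_by_registration_order(self.outer_sizes)
        fit_part, valid_part = train.split_by_registration_order(self.inner_sizes)

        recipe = fit_recipe(fit_part, self.missing_threshold, self.r_threshold, self.keep_priority)

        models: dict[str, UpliftModel] = {}
        summaries: list[qini.QiniSummary] = []
        v_arm = valid_part.data["arm"].to_numpy()
        v_succ = valid_part.data["success"].to_numpy()
        for cid in self.classifier_ids:
            m = fit_uplift_model(fit_part, cid, recipe, seed=self.seed)
            models[cid] = m
            scores_v = uplift_scores(m, valid_part)
            summaries.append(qini.build_summary(scores_v, v_arm, v_succ, classifier_id=cid))

        selected = qini.select_best_model(summaries)
        sel_summary = next(s for s in summaries if s.classifier_id == selected)
        cutoff, no_benefit = sel_summary.optimal_cutoff, sel_summary.no_benefit

        # --- model and cutoff are frozen; test data are first touched here ---
        warnings_list: list[str] = []
        if no_benefit:
            warnings_list.append(
                "no-benefit cutoff: validation Qini curve never exceeded the diagonal; "
                "all test subjects fall in the low stratum"
            )
        test_scores = uplift_scores(models[selected], test)
        strata = evaluation.stratify_by_cutoff(test_scores, cutoff)

        t = test.data
        comparisons: dict[str, StratumComparison] = {}
        for label in (STRATUM_HIGH, STRATUM_LOW):
            mask = strata == label
            if mask.sum() == 0:
                warnings_list.append(f"degenerate stratum: {label!r} is empty on the test set")
                comparisons[label] = StratumComparison(
                    stratum=label, n_treatment=0, n_control=0, events_treatment=0,
                    events_control=0, km_treatment=None, km_control=None, logrank_p=None,
                    hazard_ratio=None, ci95=None, cox_p=None, warning="empty stratum")
                continue
            comp = evaluation.compare_stratum(
                t.loc[mask, "event_time"], t.loc[mask, "event_indicator"], t.loc[mask, "arm"], label)
            if comp.warning:
                warnings_list.append(comp.warning)
            comparisons[label] = comp

        interaction: InteractionResult | None = None
        cells_ok = all(
            ((strata == s) & (t["arm"] == a)).sum() > 0
            for s in (STRATUM_HIGH, STRATUM_LOW) for a in ("treatment", "control")
        )
        if cells_ok and t["event_indicator"].sum() > 0:
            interaction = evaluation.cox_interaction(
                t["event_time"], t["event_indicator"], t["arm"], strata)
        else:
            warnings_list.append("interaction test skipped: empty arm-by-stratum cell or no events")

        schoenfeld = None
        if t["event_indicator"].sum() >= 2 and t["arm"].nunique() == 2:
            overall_cox = evaluation.cox_treatment_hr(t["event_time"], t["event_indicator"], t["arm"])
            schoenfeld = evaluation.schoenfeld_check(overall_cox)

        char_by_stratum = evaluation.characteristics_table(test, strata)
        char_by_arm: dict[str, pd.DataFrame] = {}
        for label in (STRATUM_HIGH, STRATUM_LOW):
            mask = strata == label
            if mask.sum() and t.loc[mask, "arm"].nunique() == 2:
                sub = CohortTable(t.loc[mask], test.schema, horizon=test.horizon)
                char_by_arm[label] = evaluation.characteristics_table(sub, sub.data["arm"].to_numpy())

        return UpliftTrialResults(
            model=self,
            recipe=recipe,
            qini_summaries=summaries,
            selected_classifier=selected,
            selected_model=models[selected],
            cutoff=cutoff,
            no_benefit=no_benefit,
            test_scores=test_scores,
            test_strata=strata,
            comparisons=comparisons,
            interaction=interaction,
            schoenfeld=schoenfeld,
            characteristics_by_stratum=char_by_stratum,
            characteristics_by_arm=char_by_arm,
            warnings=warnings_list,
            split_sizes={"outer": (train.n, test.n), "inner": (fit_part.n, valid_part.n)},
        )


@dataclass
class UpliftTrialResults:
    """Fitted-pipeline results: selection table, cutoff, and test-set validation."""

    model: UpliftTrialModel
    recipe: PreprocessRecipe
    qini_summaries: list
    selected_classifier: str
    selected_model: UpliftModel
    cutoff: float
    no_benefit: bool
    test_scores: np.ndarray
    test_strata: np.ndarray
    comparisons: dict[str, StratumComparison]
    interaction: InteractionResult | None
    schoenfeld: dict | None
    characteristics_by_stratum: pd.DataFrame
    characteristics_by_arm: dict[str, pd.DataFrame]
    warnings: list[str]
    split_sizes: dict

    # -- views -------------------------------------------------------------
    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "classifier_id": s.classifier_id,
                    "qini_coefficient": s.qini_coefficient,
                    "optimal_cutoff": s.optimal_cutoff,
                    "no_benefit": s.no_benefit,
                    "selected": s.classifier_id == self.selected_classifier,
                }
                for s in self.qini_summaries
            ]
        )

    def stratified_outcomes(self) -> dict:
        out = {}
        for label, c in self.comparisons.items():
            out[label] = {
                "n_treatment": c.n_treatment,
                "n_control": c.n_control,
                "events_treatment": c.events_treatment,
                "events_control": c.events_control,
                "event_fraction_treatment": c.event_fraction_treatment,
                "event_fraction_control": c.event_fraction_control,
                "hazard_ratio": c.hazard_ratio,
                "ci95": list(c.ci95) if c.ci95 else None,
                "cox_p": c.cox_p,
                "logrank_p": c.logrank_p,
                "flagged": c.flagged,
                "warning": c.warning,
            }
        out["interaction_p"] = self.interaction.interaction_p if self.interaction else None
        out["schoenfeld"] = self.schoenfeld["p"] if self.schoenfeld else None
        out["cutoff"] = self.cutoff
        out["no_benefit"] = self.no_benefit
        out["selected_classifier"] = self.selected_classifier
        out["warnings"] = self.warnings
        return out

    def summary(self) -> str:
        """Human-readable report of selection, cutoff, and stratified outcomes."""
        lines = [
            "Uplift trial analysis",
            "=====================",
            f"cohort n={self.model.cohort.n}; splits outer={self.split_sizes['outer']}, "
            f"inner={self.split_sizes['inner']}",
            f"kept features ({len(self.recipe.kept_features)}): {', '.join(self.recipe.kept_features)}",
            "",
            "Model selection (validation Qini coefficient):",
        ]
        for _, row in self.selection_table().iterrows():
            mark = " <- selected" if row["selected"] else ""
            lines.append(f"  {row['classifier_id']:<32} Q={row['qini_coefficient']:8.3f}"
                         f"  cutoff={row['optimal_cutoff']:.4f}{mark}")
        cutoff_txt = "no-benefit (+inf)" if self.no_benefit else f"{self.cutoff:.4f}"
        lines += ["", f"Selected: {self.selected_classifier}; uplift-score cutoff = {cutoff_txt}", ""]
        for label in (STRATUM_HIGH, STRATUM_LOW):
            c = self.comparisons.get(label)
            if c is None:
                continue
            lines.append(f"Test stratum '{label}' (score {'>=' if label == STRATUM_HIGH else '<'} cutoff): "
                         f"n={c.n_treatment + c.n_control}")
            lines.append(f"  treatment: {c.events_treatment}/{c.n_treatment} events"
                         f" ({100 * c.event_fraction_treatment:.1f}%)" if c.n_treatment else "  treatment: empty")
            lines.append(f"  control:   {c.events_control}/{c.n_control} events"
                         f" ({100 * c.event_fraction_control:.1f}%)" if c.n_control else "  control: empty")
            if c.hazard_ratio is not None:
                lines.append(f"  HR {c.hazard_ratio:.2f} (95% CI {c.ci95[0]:.2f}-{c.ci95[1]:.2f});"
                             f" Cox p={c.cox_p:.3f}; log-rank p={c.logrank_p:.3f}")
            if c.warning:
                lines.append(f"  WARNING: {c.warning}")
        if self.interaction is not None:
            lines.append(f"Treatment-by-stratum interaction p = {self.interaction.interaction_p:.3f}")
        if self.schoenfeld is not None:
            ok = "pass" if self.schoenfeld["pass"] else "FAIL"
            ps = ", ".join(f"{k}={v:.3f}" for k, v in self.schoenfeld["p"].items())
            lines.append(f"Schoenfeld proportional-hazards check: {ok} ({ps})")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)

    # -- export ------------------------------------------------------------
    def export(self, directory: str | Path, config: PipelineConfig | None = None) -> list[Path]:
        """Write selection table, Qini curves (+plot), stratified outcomes, tables, summary.

        Deterministic: re-exporting the same results yields identical bytes.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _w(path: Path):
            written.append(path)
            return path

        self.selection_table().to_csv(_w(directory / "model_selection.csv"), index=False)
        for s in self.qini_summaries:
            qini.curve_frame(s).to_csv(_w(directory / f"qini_{s.classifier_id}.csv"), index=False)
        qini.plot_qini_curves(self.qini_summaries, _w(directory / "qini_curves.png"))
        (_w(directory / "stratified_outcomes.json")).write_text(
            json.dumps(self.stratified_outcomes(), indent=2, default=float))
        self.characteristics_by_stratum.to_csv(_w(directory / "characteristics_test_by_stratum.csv"))
        for label, tab in self.characteristics_by_arm.items():
            tab.to_csv(_w(directory / f"characteristics_{label}_by_arm.csv"))
        for label, c in self.comparisons.items():
            for arm_name, km in (("treatment", c.km_treatment), ("control", c.km_control)):
                if km is not None:
                    km.to_csv(_w(directory / f"km_{label}_{arm_name}.csv"), index=False)
        # forest-plot style content: one row per stratum
        pd.DataFrame(
            [
                {
                    "stratum": label,
                    "hazard_ratio": c.hazard_ratio,
                    "ci_low": c.ci95[0] if c.ci95 else None,
                    "ci_high": c.ci95[1] if c.ci95 else None,
                    "cox_p": c.cox_p,
                    "interaction_p": self.interaction.interaction_p if self.interaction else None,
                }
                for label, c in self.comparisons.items()
            ]
        ).to_csv(_w(directory / "forest_plot.csv"), index=False)
        (_w(directory / "summary.txt")).write_text(self.summary() + "\n")
        prov = {
            "seed": self.model.seed,
            "package_version": _package_version(),
            "config_hash": config.config_hash() if config else None,
            "classifier_ids": list(self.model.classifier_ids),
        }
        (_w(directory / "provenance.json")).write_text(json.dumps(prov, indent=2))
        return written


def run_pipeline(config: PipelineConfig) -> UpliftTrialResults:
    """Build the cohort (synthetic or from disk), fit the model, export if configured."""
    config.validate()
    if config.synthetic is not None:
        cohort, _truth = generate_cohort(config.synthetic)
    else:
        cohort = CohortTable.from_csv(config.cohort_path, config.schema_path)
    model = UpliftTrialModel(
        cohort,
        outer_sizes=config.outer_sizes,
        inner_sizes=config.inner_sizes,
        classifier_ids=config.classifier_ids,
        missing_threshold=config.missing_threshold,
        r_threshold=config.r_threshold,
        keep_priority=config.keep_priority,
        seed=config.seed,
    )
    results = model.fit()
    if config.output_dir:
        results.export(config.output_dir, config=config)
    return results
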