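"""One-model uplift estimation via class-variable transformation.

In a 1:1 randomized trial the individual treatment effect on the success
probability,

    uplift(x) = P_T(Y=1 | X=x) - P_C(Y=1 | X=x),

can be learned with a single binary classifier. Relabel each subject

    Z = 1  if treated and successful, or control and failed
    Z = 0  otherwise,

then, because allocation is independent of X and both arms are equally
likely, uplift(x) = 2 P(Z=1 | X=x) - 1. Any probabilistic classifier for Z
therefore yields an uplift score in [-1, 1] per subject. The identity is
exact only under balanced allocation; with imbalanced arms the score is
biased (the ranking typically survives, the scale does not). Classifier
probabilities are used raw — no calibration is applied — so poorly calibrated
classifiers distort the score scale but not necessarily the ranking.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from .classifiers import make_classifier
from .cohort import ARM_CONTROL, ARM_TREATMENT, CohortTable
from .preprocess import PreprocessRecipe, apply_recipe


def transform_class_variable(arm, success):
    """Z = 1 for (treatment & success) or (control & failure); 0 otherwise.

    Accepts scalars or aligned arrays.
    """
    arm_arr = np.asarray(arm, dtype=object)
    succ = np.asarray(success, dtype=int)
    scalar = arm_arr.ndim == 0
    arm_arr = np.atleast_1d(arm_arr)
    succ = np.atleast_1d(succ)
    bad = set(np.unique(arm_arr)) - {ARM_TREATMENT, ARM_CONTROL}
    if bad:
        raise ValueError(f"unknown arm labels: {sorted(bad)}")
    if not np.isin(succ, (0, 1)).all():
        raise ValueError("success must be binary")
    treated = arm_arr == ARM_TREATMENT
    z = np.where(treated, succ, 1 - succ).astype(int)
    return int(z[0]) if scalar else z


@dataclass
class UpliftModel:
    """A fitted P(Z=1|X) classifier bundled with its preprocessing recipe."""

    classifier_id: str
    estimator: Pipeline                 # one-hot encoding + classifier
    recipe: PreprocessRecipe
    encoded_feature_map: list[str]      # source feature per encoded design column
    training_fingerprint: str


def _design_columns(recipe: PreprocessRecipe) -> tuple[list[str], list[str]]:
    return list(recipe.kept_continuous), list(recipe.kept_categorical)


def fit_uplift_model(train: CohortTable, classifier_id: str, recipe: PreprocessRecipe,
                     seed: int = 0, **hyperparameters) -> UpliftModel:
    """Fit the transformed-label classifier on a training cohort.

    The recipe must have been fitted on this same training cohort (or an
    ancestor of it); categorical features are one-hot encoded inside the model
    boundary with the imputation level "not available" as an ordinary level.
    Deterministic given (data, classifier_id, seed).
    """
    arms = set(train.data["arm"].unique())
    if arms != {ARM_TREATMENT, ARM_CONTROL}:
        raise ValueError("training cohort must contain both arms")

    X = apply_recipe(recipe, train)
    z = transform_class_variable(train.data["arm"].to_numpy(), train.data["success"].to_numpy())
    if len(np.unique(z)) < 2:
        raise ValueError("degenerate fit: transformed class variable is single-valued in training data")

    cont, cat = _design_columns(recipe)
    encoder = ColumnTransformer(
        [("onehot", OneHotEncoder(handle_unknown="ignore", sparse_output=False), cat)],
        remainder="passthrough",
        verbose_feature_names_out=False,
    )
    clf = make_classifier(classifier_id, seed=seed, **hyperparameters)
    pipe = Pipeline([("encode", encoder), ("clf", clf)])
    pipe.fit(X, z)

    # map encoded design columns back to source features (for importance reports)
    onehot = pipe.named_steps["encode"].named_transformers_["onehot"]
    feature_map: list[str] = []
    if cat:
        for feat, cats in zip(cat, onehot.categories_):
            feature_map.extend([feat] * len(cats))
    feature_map.extend(cont)  # passthrough columns follow the encoded block

    fingerprint = hashlib.sha256(
        X.to_csv(index=False).encode() + z.tobytes() + classifier_id.encode() + str(seed).encode()
    ).hexdigest()

    return UpliftModel(
        classifier_id=classifier_id,
        estimator=pipe,
        recipe=recipe,
        encoded_feature_map=feature_map,
        training_fingerprint=fingerprint,
    )


def predict_z_probability(model: UpliftModel, cohort: CohortTable) -> np.ndarray:
    """P(Z=1|X) for every subject in the cohort, in cohort order."""
    X = apply_recipe(model.recipe, cohort)
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    p = proba[:, classes.index(1)]
    return np.clip(p, 0.0, 1.0)


def uplift_scores(model: UpliftModel, cohort: CohortTable) -> np.ndarray:
    """Per-subject uplift score 2 P(Z=1|X) - 1, bounded in [-1, 1]."""
    return 2.0 * predict_z_probability(model, cohort) - 1.0


def export_scores(model: UpliftModel, cohort: CohortTable, path) -> pd.DataFrame:
    """Write (subject_id, probability, uplift_score) as CSV; returns the frame."""
    p = predict_z_probability(model, cohort)
    df = pd.DataFrame(
        {"subject_id": cohort.data["subject_id"], "probability": p, "uplift_score": 2 * p - 1}
    )
    df.to_csv(path, index=False)
    return df
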