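"""Pluggable registry of probabilistic classifiers for uplift fitting.

Every entry implements the scikit-learn fit / predict_proba contract and is
constructed fresh per fit with a caller-supplied seed. The mandatory set spans
the linear, instance-based, Bayes, discriminant and tree/boosting families;
heavier families (SVM with probabilities, Gaussian process, MLP, extra trees,
XGBoost, LightGBM) register as optional plugins when their libraries import.

Gini (impurity-decrease) feature importance is exposed for tree ensembles,
with one-hot dummy columns aggregated back to their source features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


class RegistryError(KeyError):
    """Unknown or duplicate classifier id."""


class CapabilityError(TypeError):
    """The classifier does not support the requested capability."""


@dataclass(frozen=True)
class ClassifierSpec:
    id: str
    factory: Callable[..., object]       # factory(seed=..., **hyperparameters)
    supports_importance: bool
    hyperparameters: dict = field(default_factory=dict)
    mandatory: bool = False


_REGISTRY: dict[str, ClassifierSpec] = {}


def register_classifier(spec: ClassifierSpec, overwrite: bool = False) -> None:
    if spec.id in _REGISTRY and not overwrite:
        raise RegistryError(f"classifier id already registered: {spec.id!r}")
    _REGISTRY[spec.id] = spec


def available_classifiers() -> list[ClassifierSpec]:
    """Registered classifiers in registration order (mandatory set first)."""
    return list(_REGISTRY.values())


def get_spec(classifier_id: str) -> ClassifierSpec:
    try:
        return _REGISTRY[classifier_id]
    except KeyError:
        raise RegistryError(f"unknown classifier id: {classifier_id!r}") from None


def make_classifier(classifier_id: str, seed: int = 0, **overrides):
    """Instantiate a fresh, unfitted classifier with the registry defaults."""
    spec = get_spec(classifier_id)
    params = {**spec.hyperparameters, **overrides}
    return spec.factory(seed=seed, **params)


# ---------------------------------------------------------------------------
# built-in factories
# ---------------------------------------------------------------------------

def _logistic(seed=0, **kw):
    from sklearn.linear_model import LogisticRegression
    return LogisticRegression(max_iter=1000, random_state=seed, **kw)


def _decision_tree(seed=0, **kw):
    from sklearn.tree import DecisionTreeClassifier
    return DecisionTreeClassifier(random_state=seed, **kw)


def _random_forest(seed=0, **kw):
    from sklearn.ensemble import RandomForestClassifier
    return RandomForestClassifier(n_estimators=100, random_state=seed, **kw)


def _adaboost(seed=0, **kw):
    from sklearn.ensemble import AdaBoostClassifier
    return AdaBoostClassifier(n_estimators=50, random_state=seed, **kw)


def _gradient_boosting(seed=0, **kw):
    from sklearn.ensemble import GradientBoostingClassifier
    return GradientBoostingClassifier(random_state=seed, **kw)


def _naive_bayes(seed=0, **kw):
    from sklearn.naive_bayes import GaussianNB
    return GaussianNB(**kw)


def _knn(seed=0, **kw):
    from sklearn.neighbors import KNeighborsClassifier
    return KNeighborsClassifier(**kw)


def _lda(seed=0, **kw):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    return LinearDiscriminantAnalysis(**kw)


def _qda(seed=0, **kw):
    from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
    # one-hot designs make per-class covariances rank-deficient; a small
    # regularizer keeps QDA well-posed on such data
    kw.setdefault("reg_param", 0.1)
    return QuadraticDiscriminantAnalysis(**kw)


MANDATORY_CLASSIFIERS = (
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "adaptive_boosting",
    "gradient_boosting",
    "naive_bayes",
    "k_nearest_neighbors",
    "linear_discriminant_analysis",
    "quadratic_discriminant_analysis",
)

register_classifier(ClassifierSpec("logistic_regression", _logistic, False, mandatory=True))
register_classifier(ClassifierSpec("decision_tree", _decision_tree, True, mandatory=True))
register_classifier(ClassifierSpec("random_forest", _random_forest, True, mandatory=True))
register_classifier(ClassifierSpec("adaptive_boosting", _adaboost, True, mandatory=True))
register_classifier(ClassifierSpec("gradient_boosting", _gradient_boosting, True, mandatory=True))
register_classifier(ClassifierSpec("naive_bayes", _naive_bayes, False, mandatory=True))
register_classifier(ClassifierSpec("k_nearest_neighbors", _knn, False, mandatory=True))
register_classifier(ClassifierSpec("linear_discriminant_analysis", _lda, False, mandatory=True))
register_classifier(ClassifierSpec("quadratic_discriminant_analysis", _qda, False, mandatory=True))


def _svm_rbf(seed=0, **kw):
    from sklearn.svm import SVC
    return SVC(kernel="rbf", probability=True, random_state=seed, **kw)


def _extra_trees(seed=0, **kw):
    from sklearn.ensemble import ExtraTreesClassifier
    return ExtraTreesClassifier(n_estimators=100, random_state=seed, **kw)


def _gaussian_process(seed=0, **kw):
    from sklearn.gaussian_process import GaussianProcessClassifier
    return GaussianProcessClassifier(random_state=seed, **kw)


def _mlp(seed=0, **kw):
    from sklearn.neural_network import MLPClassifier
    return MLPClassifier(max_iter=500, random_state=seed, **kw)


register_classifier(ClassifierSpec("svm_rbf", _svm_rbf, False))
register_classifier(ClassifierSpec("extra_trees", _extra_trees, True))
register_classifier(ClassifierSpec("gaussian_process", _gaussian_process, False))
register_classifier(ClassifierSpec("multilayer_perceptron", _mlp, False))

try:  # optional gradient-boosting plugins
    import xgboost  # noqa: F401

    def _xgb(seed=0, **kw):
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, verbosity=0, use_label_encoder=False,
                             eval_metric="logloss", **kw)

    register_classifier(ClassifierSpec("extreme_gradient_boosting", _xgb, True))
except ImportError:  # pragma: no cover
    pass

try:
    import lightgbm  # noqa: F401

    def _lgbm(seed=0, **kw):
        from lightgbm import LGBMClassifier
        return LGBMClassifier(random_state=seed, verbose=-1, **kw)

    register_classifier(ClassifierSpec("light_gradient_boosting", _lgbm, True))
except ImportError:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def gini_importance(model) -> list[tuple[str, float]]:
    """Impurity-based importance per *source* feature, descending, summing to 1.

    ``model`` is a fitted :class:`~uplift_rct.uplift.UpliftModel`. One-hot
    dummy columns are aggregated back to the categorical feature they encode.
    """
    spec = get_spec(model.classifier_id)
    if not spec.supports_importance:
        raise CapabilityError(f"{model.classifier_id!r} does not expose impurity-based importance")
    clf = model.estimator[-1]
    raw = np.asarray(clf.feature_importances_, dtype=float)
    if len(raw) != len(model.encoded_feature_map):
        raise RuntimeError("importance vector does not match the encoded design matrix")
    agg: dict[str, float] = {}
    for src, imp in zip(model.encoded_feature_map, raw):
        agg[src] = agg.get(src, 0.0) + float(imp)
    total = sum(agg.values())
    if total > 0:
        agg = {k: v / total for k, v in agg.items()}
    return sorted(agg.items(), key=lambda kv: kv[1], reverse=True)
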