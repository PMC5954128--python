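"""The six base classifiers behind one train/predict contract.

Method tags: ``tree`` (pruned decision tree), ``rf`` (random forest, 100
trees), ``svm`` (polynomial-kernel support vector machine), ``ann``
(multilayer perceptron), ``knn`` (k nearest neighbors, k=5) and ``logreg``
(logistic regression). Internals are delegated to scikit-learn estimators;
the contract here is the shared train/predict/cross-validate behavior on
:class:`~alboost.data_io.FeatureTable` inputs. Labels are encoded as the
index into ``class_names`` (positive class = 0), so prediction ties break
toward the lower class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_io import FeatureTable
from .metrics import ConfusionCounts, confusion

__all__ = [
    "METHODS",
    "LearnerSpec",
    "TrainedLearner",
    "CVResult",
    "train_learner",
    "predict",
    "cross_validate",
]

METHODS = ("tree", "rf", "svm", "ann", "knn", "logreg")

#: Display names used in reports.
METHOD_LABELS = {
    "tree": "J4.8",
    "rf": "RF",
    "svm": "SVM",
    "ann": "ANN",
    "knn": "k-NN",
    "logreg": "LR",
}


@dataclass
class LearnerSpec:
    """A method tag plus hyperparameters and a seed for stochastic methods."""

    method: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")


def _build_estimator(spec: LearnerSpec):
    p = dict(spec.params)
    if spec.method == "tree":
        return DecisionTreeClassifier(
            ccp_alpha=p.pop("ccp_alpha", 0.0),
            random_state=spec.seed,
            **p,
        )
    if spec.method == "rf":
        return RandomForestClassifier(
            n_estimators=p.pop("n_trees", 100), random_state=spec.seed, **p
        )
    if spec.method == "svm":
        return SVC(
            kernel="poly",
            degree=p.pop("degree", 1),
            C=p.pop("C", 1.0),
            coef0=p.pop("coef0", 0.0),
            **p,
        )
    if spec.method == "ann":
        layers = p.pop("layers", [19] * 19)
        return MLPClassifier(
            hidden_layer_sizes=tuple(layers),
            max_iter=p.pop("max_iter", 500),
            random_state=spec.seed,
            **p,
        )
    if spec.method == "knn":
        return KNeighborsClassifier(n_neighbors=p.pop("k", 5), **p)
    if spec.method == "logreg":
        return LogisticRegression(max_iter=p.pop("max_iter", 1000), **p)
    raise AssertionError(spec.method)


@dataclass
class TrainedLearner:
    spec: LearnerSpec
    estimator: Any
    feature_names: list[str]
    class_names: tuple[str, str]


@dataclass
class CVResult:
    folds: int
    fold_confusions: list[ConfusionCounts]
    pooled: ConfusionCounts
    ccr_error: float
    oof_predictions: np.ndarray   # out-of-fold predicted labels, one per training row


def train_learner(spec: LearnerSpec, train: FeatureTable) -> TrainedLearner:
    """Fit one base classifier. Deterministic given the spec's seed."""
    counts = train.class_counts()
    if min(counts.values()) == 0:
        raise ValueError(f"training data contains a single class: {counts}")
    est = _build_estimator(spec)
    est.fit(train.matrix, train.y)
    return TrainedLearner(
        spec=spec,
        estimator=est,
        feature_names=list(train.feature_names),
        class_names=train.class_names,
    )


def predict(model: TrainedLearner, table: FeatureTable) -> np.ndarray:
    """Per-compound class labels, from the two classes declared at training."""
    if list(table.feature_names) != model.feature_names:
        raise ValueError("feature names/order do not match the training table")
    yhat = model.estimator.predict(table.matrix)
    return np.asarray(model.class_names, dtype=object)[yhat]


def cross_validate(
    spec: LearnerSpec, train: FeatureTable, folds: int = 10, seed: int = 0
) -> CVResult:
    """Stratified k-fold cross-validation with pooled out-of-fold counts.

    The CCR error (1 - balanced accuracy) is computed on the confusion
    counts pooled across the held-out folds. Fold assignment is
    deterministic given `seed` and identical for every learner that is
    passed the same seed, so learners are compared on the same folds.
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    counts = train.class_counts()
    if min(counts.values()) < folds:
        raise ValueError(f"every class must have at least {folds} compounds: {counts}")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty(train.n, dtype=object)
    fold_confusions: list[ConfusionCounts] = []
    for fit_idx, held_idx in splitter.split(train.matrix, train.y):
        model = train_learner(spec, train.select(fit_idx))
        held = train.select(held_idx)
        yhat = predict(model, held)
        oof[held_idx] = yhat
        fold_confusions.append(
            confusion(held.labels, yhat, train.class_names[0], train.class_names)
        )
    pooled = confusion(train.labels, oof, train.class_names[0], train.class_names)
    sens = pooled.tp / pooled.n_pos
    spec_rate = pooled.tn / pooled.n_neg
    return CVResult(
        folds=folds,
        fold_confusions=fold_confusions,
        pooled=pooled,
        ccr_error=1.0 - (sens + spec_rate) / 2,
        oof_predictions=oof,
    )
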