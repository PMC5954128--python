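"""The AL Boost ensemble: CCR-error-weighted majority voting.

Each base learner first earns a weight w_i — its corrected-classification-
rate error from cross-validation on the training set (floored at a small
epsilon so a perfect learner keeps finite voting power) — and is then
refit on the full training set. At prediction time every learner casts a
vote and two scores are accumulated per compound:

    f(active)   = sum_i (1/w_i) [learner i votes active]
    f(inactive) = sum_i (1/w_i) [learner i votes inactive]

so poor learners (large CCR error) carry little voting power. The larger
score wins; an exact tie defers to the single most accurate learner's
vote, and failing that to the active class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureTable
from .learners import (
    CVResult,
    LearnerSpec,
    TrainedLearner,
    cross_validate,
    predict,
    train_learner,
)

__all__ = ["EnsembleModel", "VoteScores", "fit_alboost", "vote", "alboost_predict",
           "vote_from_predictions", "weighted_vote_labels",
           "save_ensemble", "load_ensemble"]

DEFAULT_EPSILON = 1e-6


@dataclass
class EnsembleModel:
    learners: list[TrainedLearner]
    weights: np.ndarray             # per-learner CCR error, epsilon-floored
    epsilon: float
    cv_results: list[CVResult]
    class_names: tuple[str, str]

    @property
    def tie_breaker(self) -> int:
        """Index of the most accurate learner (lowest weight, first on ties)."""
        return int(np.argmin(self.weights))


@dataclass
class VoteScores:
    f_active: np.ndarray            # per-compound weighted mass for the positive class
    f_inactive: np.ndarray
    votes: np.ndarray               # learners x compounds, 1 where learner voted active


def fit_alboost(
    specs: list[LearnerSpec],
    train: FeatureTable,
    folds: int = 10,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
) -> EnsembleModel:
    """Cross-validate each learner for its weight, then refit on all of train.

    All learners are cross-validated on the same fold assignment (derived
    from `seed`), so their CCR errors are directly comparable.
    """
    if len(specs) < 1:
        raise ValueError("need at least one learner spec")
    cv_results = [cross_validate(s, train, folds=folds, seed=seed) for s in specs]
    weights = np.array([max(r.ccr_error, epsilon) for r in cv_results])
    learners = [train_learner(s, train) for s in specs]
    return EnsembleModel(
        learners=learners,
        weights=weights,
        epsilon=epsilon,
        cv_results=cv_results,
        class_names=train.class_names,
    )


def vote_from_predictions(
    predictions: np.ndarray,
    weights: np.ndarray,
    class_names: tuple[str, str],
) -> VoteScores:
    """Weighted vote masses from a learners-x-compounds label matrix."""
    preds = np.asarray(predictions, dtype=object)
    votes = (preds == class_names[0]).astype(float)
    power = (1.0 / np.asarray(weights, dtype=float))[:, None]
    return VoteScores(
        f_active=(power * votes).sum(axis=0),
        f_inactive=(power * (1.0 - votes)).sum(axis=0),
        votes=votes.astype(int),
    )


def vote(model: EnsembleModel, table: FeatureTable) -> VoteScores:
    """Per-compound weighted vote masses for both classes."""
    predictions = np.stack([predict(m, table) for m in model.learners])
    return vote_from_predictions(predictions, model.weights, model.class_names)


def alboost_predict(model: EnsembleModel, table: FeatureTable) -> np.ndarray:
    """Majority of weighted vote mass; ties defer to the best learner, then active."""
    scores = vote(model, table)
    return _labels_from_scores(
        scores.f_active,
        scores.f_inactive,
        scores.votes[model.tie_breaker],
        model.class_names,
    )


def weighted_vote_labels(
    predictions: np.ndarray,
    weights: np.ndarray,
    class_names: tuple[str, str],
) -> np.ndarray:
    """Combine a learners-x-compounds label matrix by 1/w weighted voting.

    Used to score the ensemble on out-of-fold cross-validation predictions
    without refitting; applies the same tie-break rule as prediction.
    """
    scores = vote_from_predictions(predictions, weights, class_names)
    best = int(np.argmin(np.asarray(weights, dtype=float)))
    return _labels_from_scores(
        scores.f_active, scores.f_inactive, scores.votes[best], class_names
    )


def save_ensemble(model: EnsembleModel, path, norm_stats=None) -> None:
    """Pickle a fitted ensemble (optionally with its normalization stats)."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"ensemble": model, "norm_stats": norm_stats}, fh)


def load_ensemble(path) -> tuple[EnsembleModel, object]:
    """Load a pickled ensemble; returns (model, norm_stats-or-None)."""
    import pickle

    with open(path, "rb") as fh:
        bundle = pickle.load(fh)
    return bundle["ensemble"], bundle.get("norm_stats")


def _labels_from_scores(
    f_active: np.ndarray,
    f_inactive: np.ndarray,
    best_votes: np.ndarray,
    class_names: tuple[str, str],
) -> np.ndarray:
    active = f_active > f_inactive
    tied = f_active == f_inactive
    active |= tied & (best_votes > 0)
    return np.where(active, class_names[0], class_names[1]).astype(object)
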