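import numpy as np
import pytest

from alboost.ensemble import (
    alboost_predict,
    fit_alboost,
    vote,
    vote_from_predictions,
    weighted_vote_labels,
)
from alboost.learners import LearnerSpec, predict
from alboost.metrics import compute_report, confusion

CLASSES = ("drug", "nondrug")
FAST_ANN = {"ann": {"layers": [19], "max_iter": 400}}


def _specs(methods, seed=0):
    return [LearnerSpec(m, dict(FAST_ANN.get(m, {})), seed=seed) for m in methods]


class TestWeights:
    def test_perfect_learner_weight_floored(self, separable_table):
        model = fit_alboost(_specs(["knn"]), separable_table, folds=5, seed=0)
        assert model.cv_results[0].ccr_error == 0.0
        assert model.weights[0] == pytest.approx(1e-6)

    def test_identical_specs_identical_weights(self, moderate_table):
        model = fit_alboost(_specs(["rf", "rf"]), moderate_table, folds=5, seed=0)
        assert model.weights[0] == model.weights[1]

    def test_voting_power_is_reciprocal_error(self):
        scores = vote_from_predictions(
            np.array([["drug"], ["drug"], ["drug"]], dtype=object),
            [0.2, 0.3, 0.4],
            CLASSES,
        )
        assert scores.f_active[0] == pytest.approx(5.0 + 1 / 0.3 + 2.5)
        np.testing.assert_allclose(1.0 / np.array([0.2, 0.3, 0.4]),
                                   [5.0, 10 / 3, 2.5])


class TestVoteArithmetic:
    def test_worked_split_vote(self):
        """Errors {0.2, 0.3, 0.4}, votes {active, inactive, inactive}:
        f_active = 5.0, f_inactive = 5.83 -> inactive wins."""
        preds = np.array([["drug"], ["nondrug"], ["nondrug"]], dtype=object)
        weights = np.array([0.2, 0.3, 0.4])
        scores = vote_from_predictions(preds, weights, CLASSES)
        assert scores.f_active[0] == pytest.approx(5.0)
        assert scores.f_inactive[0] == pytest.approx(1 / 0.3 + 1 / 0.4)  # 5.83...
        assert weighted_vote_labels(preds, weights, CLASSES)[0] == "nondrug"

    def test_unanimous_vote_zeroes_the_other_score(self):
        preds = np.array([["drug"], ["drug"], ["drug"]], dtype=object)
        scores = vote_from_predictions(preds, [0.2, 0.3, 0.4], CLASSES)
        assert scores.f_inactive[0] == 0.0

    def test_scores_sum_to_total_voting_power(self, moderate_table):
        model = fit_alboost(
            _specs(["tree", "knn", "logreg"]), moderate_table, folds=5, seed=0
        )
        scores = vote(model, moderate_table)
        np.testing.assert_allclose(
            scores.f_active + scores.f_inactive, (1.0 / model.weights).sum()
        )

    def test_single_learner_score_shape(self):
        preds = np.array([["drug", "nondrug"]], dtype=object)
        scores = vote_from_predictions(preds, [0.25], CLASSES)
        np.testing.assert_allclose(scores.f_active, [4.0, 0.0])
        np.testing.assert_allclose(scores.f_inactive, [0.0, 4.0])


class TestReductions:
    def test_single_learner_is_identity(self, moderate_table):
        model = fit_alboost(_specs(["tree"]), moderate_table, folds=5, seed=0)
        np.testing.assert_array_equal(
            alboost_predict(model, moderate_table),
            predict(model.learners[0], moderate_table),
        )

    def test_equal_weights_reduce_to_simple_majority(self):
        rng = np.random.default_rng(0)
        preds = np.array(
            [[CLASSES[rng.integers(2)] for _ in range(40)] for _ in range(5)],
            dtype=object,
        )
        got = weighted_vote_labels(preds, [0.3] * 5, CLASSES)
        majority = np.where(
            (preds == "drug").sum(axis=0) > 2.5, "drug", "nondrug"
        ).astype(object)
        np.testing.assert_array_equal(got, majority)

    def test_dominant_learner_decides_everything(self):
        rng = np.random.default_rng(1)
        preds = np.array(
            [[CLASSES[rng.integers(2)] for _ in range(30)] for _ in range(4)],
            dtype=object,
        )
        weights = np.array([1e-6, 0.5, 0.5, 0.5])  # power 1e6 vs 2+2+2
        np.testing.assert_array_equal(
            weighted_vote_labels(preds, weights, CLASSES), preds[0]
        )

    def test_learner_order_does_not_change_predictions(self):
        rng = np.random.default_rng(2)
        preds = np.array(
            [[CLASSES[rng.integers(2)] for _ in range(50)] for _ in range(3)],
            dtype=object,
        )
        weights = np.array([0.2, 0.3, 0.4])  # powers 5, 3.33, 2.5: no exact ties
        base = weighted_vote_labels(preds, weights, CLASSES)
        perm = [2, 0, 1]
        np.testing.assert_array_equal(
            weighted_vote_labels(preds[perm], weights[perm], CLASSES), base
        )

    def test_tie_defers_to_most_accurate_learner(self):
        preds = np.array([["drug"], ["nondrug"]], dtype=object)
        # equal weights: exact tie; first (equally best) learner voted drug
        assert weighted_vote_labels(preds, [0.3, 0.3], CLASSES)[0] == "drug"
        # the better learner voted nondrug
        assert weighted_vote_labels(preds, [0.4, 0.4 - 1e-9], CLASSES)[0] == "nondrug"


class TestEnsemblePerformance:
    def test_tracks_the_best_individual_learner(self, moderate_table):
        # interleave so both classes appear in train and test (classes are
        # stored in blocks of 60)
        test_idx = np.concatenate([np.arange(45, 60), np.arange(105, 120)])
        train_idx = np.setdiff1d(np.arange(120), test_idx)
        train = moderate_table.select(train_idx)
        test = moderate_table.select(test_idx)
        specs = _specs(["tree", "rf", "knn", "logreg"])
        model = fit_alboost(specs, train, folds=5, seed=0)
        ccrs = []
        for learner in model.learners:
            counts = confusion(test.labels, predict(learner, test), "drug", CLASSES)
            ccrs.append(compute_report(counts).ccr)
        ens = compute_report(
            confusion(test.labels, alboost_predict(model, test), "drug", CLASSES)
        ).ccr
        assert ens >= max(ccrs) - 0.05
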