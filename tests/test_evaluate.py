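"""Classifier benchmarking: separable vs chance-level data, ROC, the
repeatability protocol, and leakage safety."""

import warnings

import numpy as np
import pytest

from emoeeg import cfs, evaluate

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


def _separable(n_per=30, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(4), n_per)
    centers = np.array([[0, 0], [6, 0], [0, 6], [6, 6]], dtype=float)
    X = centers[y] + 0.3 * rng.normal(size=(len(y), 2))
    return X, y


FAST = evaluate.EvalProtocol(total_folds=20, seed=0)


class TestCrossval:
    @pytest.mark.parametrize("clf", evaluate.CLASSIFIERS)
    def test_separable_data_recognized(self, clf):
        X, y = _separable()
        res = evaluate.crossval_accuracy(X, y, clf, FAST)
        assert res["mean_accuracy"] >= 95.0

    def test_shuffled_labels_at_chance(self):
        X, y = _separable(seed=1)
        y = np.random.default_rng(2).permutation(y)
        res = evaluate.crossval_accuracy(X, y, "lda", FAST)
        # 4 classes: chance 25%, generous binomial band
        assert 10.0 <= res["mean_accuracy"] <= 40.0

    def test_duplicated_columns_leave_lda_unchanged(self):
        X, y = _separable(seed=3)
        base = evaluate.crossval_accuracy(X, y, "lda", FAST)["mean_accuracy"]
        dup = evaluate.crossval_accuracy(np.hstack([X, X]), y, "lda", FAST)[
            "mean_accuracy"]
        assert abs(base - dup) <= 2.0

    def test_mean_equals_mean_of_folds(self):
        X, y = _separable(seed=4)
        res = evaluate.crossval_accuracy(X, y, "c45", FAST)
        assert res["mean_accuracy"] == pytest.approx(res["per_fold"].mean())
        assert len(res["per_fold"]) == 20

    def test_single_class_rejected(self):
        X = np.random.default_rng(5).normal(size=(20, 2))
        with pytest.raises(evaluate.EvalError):
            evaluate.crossval_accuracy(X, np.zeros(20), "lda", FAST)

    def test_unknown_classifier_rejected(self):
        with pytest.raises(evaluate.EvalError, match="unknown classifier"):
            evaluate.make_classifier("forest", 5)

    def test_no_leakage_from_trialwise_hash_feature(self):
        """A feature holding arbitrary unique per-trial values carries no
        generalizable class signal; honest evaluation stays at chance."""
        rng = np.random.default_rng(6)
        y = np.repeat(np.arange(4), 30)
        X = rng.permutation(len(y)).astype(float)[:, None]  # trial 'hash'
        res = evaluate.crossval_accuracy(X, y, "c45", FAST)
        assert res["mean_accuracy"] <= 45.0


class TestNestedCurve:
    def test_full_size_consistent_with_plain_crossval(self):
        rng = np.random.default_rng(7)
        y = np.repeat(np.arange(4), 25)
        X = rng.normal(size=(100, 6))
        X[:, 0] += 1.5 * y
        table = cfs.discretize(X, 4, labels=y)
        ranking = cfs.greedy_rank(table)
        curve = evaluate.nested_subset_curve(ranking, X, y, "c45", FAST,
                                             sizes=(2, 4, 6))
        full = evaluate.crossval_accuracy(X, y, "c45", FAST)
        assert curve["accuracy"][6] == pytest.approx(full["mean_accuracy"], abs=1e-9)

    def test_pure_noise_curve_flat_at_chance(self):
        rng = np.random.default_rng(8)
        y = np.repeat(np.arange(4), 25)
        X = rng.normal(size=(100, 6))
        table = cfs.discretize(X, 4, labels=y)
        ranking = cfs.greedy_rank(table)
        curve = evaluate.nested_subset_curve(ranking, X, y, "lda", FAST,
                                             sizes=(2, 4, 6))
        for acc in curve["accuracy"].values():
            assert 10.0 <= acc <= 45.0


class TestRocAuc:
    def test_one_hot_scores_perfect(self):
        y = np.array([0, 1, 2, 3] * 10)
        scores = np.eye(4)[y]
        assert evaluate.roc_auc(scores, y)["macro_auc"] == 1.0

    def test_random_scores_half(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 4, 1000)
        scores = rng.uniform(size=(1000, 4))
        assert evaluate.roc_auc(scores, y)["macro_auc"] == pytest.approx(0.5, abs=0.05)

    def test_reversed_scores_complementary(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 4, 200)
        scores = rng.uniform(size=(200, 4)) + np.eye(4)[y]
        a = evaluate.roc_auc(scores, y)["macro_auc"]
        b = evaluate.roc_auc(-scores, y)["macro_auc"]
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(evaluate.EvalError):
            evaluate.roc_auc(np.ones((5, 1)), np.zeros(5))

    def test_classifier_scores_pipeline(self):
        X, y = _separable(seed=11)
        s, yte = evaluate.classifier_scores(X, y, "lda")
        assert evaluate.roc_auc(s, yte)["macro_auc"] > 0.95


class TestRepeatability:
    def test_deterministic_given_seed(self):
        X, y = _separable(n_per=20, seed=12)
        a = evaluate.repeatability_run(X, y, "c45", seed=3)
        b = evaluate.repeatability_run(X, y, "c45", seed=3)
        np.testing.assert_array_equal(a["per_repeat"], b["per_repeat"])
        assert a["average"] == pytest.approx(np.mean(a["per_repeat"]))

    def test_accuracy_granularity(self):
        X, y = _separable(n_per=20, seed=13)
        r = evaluate.repeatability_run(X, y, "lda", test_per_emotion=8, seed=1)
        # 32 test trials: accuracies are multiples of 100/32
        steps = np.array(r["per_repeat"]) / (100.0 / 32.0)
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_too_few_trials_rejected(self):
        X, y = _separable(n_per=8, seed=14)
        with pytest.raises(evaluate.EvalError, match="trials"):
            evaluate.repeatability_run(X, y, "c45", test_per_emotion=8)
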