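import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from chemosens import evaluate, svm


class TestConfusionMetrics:
    def test_perfect_agreement(self):
        truth = np.array([1, 1, 1, -1, -1])
        cm = evaluate.confusion_metrics(truth, truth)
        assert (cm.accuracy, cm.tpr, cm.fpr) == (1.0, 1.0, 0.0)

    def test_total_disagreement(self):
        truth = np.array([1, 1, -1, -1])
        assert evaluate.confusion_metrics(-truth, truth).accuracy == 0.0

    def test_hand_counted_example(self):
        truth = np.array([1, 1, -1, -1])
        calls = np.array([1, -1, -1, -1])
        cm = evaluate.confusion_metrics(calls, truth)
        assert cm.accuracy == 0.75
        assert cm.sensitivity == 0.5
        assert cm.specificity == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate.confusion_metrics([1, -1], [1])

    def test_single_class_truth_flags_nan(self):
        with pytest.warns(UserWarning, match="single class"):
            cm = evaluate.confusion_metrics([1, 1], [1, 1])
        assert np.isnan(cm.specificity)


@pytest.mark.parametrize(
    "tpr, fpr, expected", [(1.0, 0.0, 1.0), (0.3, 0.3, 0.5), (0.8, 0.2, 0.8)]
)
def test_balanced_accuracy_auc(tpr, fpr, expected):
    assert evaluate.balanced_accuracy_auc(tpr, fpr) == pytest.approx(expected)


def pairwise_concordance(scores, truth):
    """Exhaustive Mann-Whitney counting oracle: ties count one half."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == -1]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        points, auc = evaluate.roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, -1, -1])
        assert auc == 1.0
        assert tuple(points[0]) == (0.0, 0.0) and tuple(points[-1]) == (1.0, 1.0)

    def test_three_of_four_pairs_concordant(self):
        _, auc = evaluate.roc_auc([0.9, 0.2, 0.3, 0.1], [1, 1, -1, -1])
        assert auc == pytest.approx(0.75)

    def test_all_ties_is_chance(self):
        _, auc = evaluate.roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, -1, -1])
        assert auc == pytest.approx(0.5)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        truth = rng.choice([-1, 1], size=n)
        if np.unique(truth).size < 2:
            truth[0] = -truth[1]
        # quantize scores to force some ties
        scores = np.round(rng.standard_normal(n), 1)
        _, auc = evaluate.roc_auc(scores, truth)
        assert auc == pytest.approx(pairwise_concordance(scores, truth), abs=1e-12)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(8)
        points, _ = evaluate.roc_auc(rng.standard_normal(25), rng.choice([-1, 1], 25))
        assert (np.diff(points[:, 0]) >= 0).all() and (np.diff(points[:, 1]) >= 0).all()


def naive_loocv_oracle(X, y, C=1.0):
    """Explicit per-fold enumeration with sklearn directly."""
    scores = []
    for i in range(y.size):
        rest = np.ones(y.size, dtype=bool)
        rest[i] = False
        Z = X.to_numpy().T
        mu, sd = Z[rest].mean(axis=0), Z[rest].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        clf = SVC(kernel="linear", C=C, tol=1e-6).fit((Z[rest] - mu) / sd, y[rest])
        scores.append(float(clf.decision_function(((Z[i] - mu) / sd)[None, :])[0]))
    return np.array(scores)


class TestLoocv:
    def test_separated_clusters_are_perfect(self, separable_toy):
        X, y = separable_toy
        report = evaluate.loocv(X, y)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert report.n_evaluated == 10

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_fold_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        y = np.array([1, -1] * (n // 2) + [1] * (n % 2))
        if np.sum(y == 1) < 2 or np.sum(y == -1) < 2:
            y[:4] = [1, 1, -1, -1]
        X = pd.DataFrame(rng.standard_normal((4, n)),
                         index=list("abcd"), columns=[f"S{i}" for i in range(n)])
        report = evaluate.loocv(X, y)
        assert np.allclose(report.scores, naive_loocv_oracle(X, y), atol=1e-9)

    def test_duplication_keeps_calls_per_unique_sample(self, separable_toy):
        X, y = separable_toy
        base = evaluate.loocv(X, y)
        X2 = pd.concat([X, X.add_suffix("_dup", axis=1)], axis=1)
        doubled = evaluate.loocv(X2, np.concatenate([y, y]))
        assert np.array_equal(doubled.calls[: y.size], base.calls)

    def test_requires_two_per_class(self, separable_toy):
        X, y = separable_toy
        y2 = y.copy()
        y2[y2 == -1] = 1
        y2[-1] = -1
        with pytest.raises(ValueError):
            evaluate.loocv(X, y2)


class TestQuadrantAccuracy:
    def test_all_concordant(self):
        nlg = np.array([1.0, 2.0, -1.0, -2.0])
        scores = np.array([0.5, 1.0, -0.5, -1.0])
        assert evaluate.quadrant_accuracy(scores, nlg) == 1.0

    def test_all_discordant(self):
        nlg = np.array([1.0, 2.0, -1.0, -2.0])
        assert evaluate.quadrant_accuracy(np.array([-1, -1, 1, 1.0]), nlg) == 0.0

    def test_counted_example(self):
        nlg = np.array([3, 2, 1, 0.5, -0.5, -1, -2, -3.0]) + 10.0
        scores = np.array([1, 1, 1, -1, -1, -1, 1, -1.0])  # 2 discordant of 8
        assert evaluate.quadrant_accuracy(scores, nlg) == 0.75

    def test_samples_at_mean_excluded(self):
        nlg = np.array([1.0, -1.0, 0.0])  # mean 0; third sample sits on it
        assert evaluate.quadrant_accuracy(np.array([1.0, -1.0, 5.0]), nlg) == 1.0


class TestResponseRate:
    def test_all_responders(self):
        assert evaluate.response_rate([2.88, 3.20]) == 1.0

    def test_no_responders(self):
        assert evaluate.response_rate([-0.28, -2.53]) == 0.0

    def test_zero_score_is_non_responder(self):
        assert evaluate.response_rate([1.0, -1.0, 0.0]) == pytest.approx(1 / 3)

    def test_accepts_prediction_results(self):
        results = [svm.PredictionResult("a", 1.0), svm.PredictionResult("b", -1.0)]
        assert evaluate.response_rate(results) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            evaluate.response_rate([])


class TestRateRegression:
    def test_identity(self):
        x = np.array([0.1, 0.4, 0.9])
        slope, intercept, r2 = evaluate.rate_regression(x, x)
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_constant_observed_r2_zero(self):
        _, _, r2 = evaluate.rate_regression([0.1, 0.5, 0.9], [0.3, 0.3, 0.3])
        assert r2 == 0.0

    def test_exact_collinear(self):
        slope, intercept, r2 = evaluate.rate_regression([0, 1, 2], [1, 3, 5])
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            evaluate.rate_regression([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
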