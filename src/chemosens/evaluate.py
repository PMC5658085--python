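"""Model evaluation: confusion metrics, ROC/AUC, LOOCV, quadrant concordance,
cohort response rates and predicted-vs-observed rate regression.

Two "AUC" quantities coexist deliberately. ``balanced_accuracy_auc`` is the
single-operating-point formula (tpr - fpr + 1) / 2 — the balanced accuracy at
the sign threshold, kept under this name for fidelity with the platform's
published description. ``roc_auc`` is the standard threshold-sweep area under
the ROC curve, equal to the Mann-Whitney concordance probability with ties
counted 1/2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from . import svm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    n: int


@dataclass(frozen=True)
class EvaluationReport:
    """LOOCV (or test-set) performance summary for one drug model."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: np.ndarray = field(repr=False)  # (n, 2) array of (fpr, tpr)
    n_evaluated: int = 0
    scores: np.ndarray = field(default=None, repr=False)
    calls: np.ndarray = field(default=None, repr=False)
    sample_ids: tuple[str, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "sensitivity", "specificity", "auc", "n_evaluated"],
                "value": [self.accuracy, self.sensitivity, self.specificity,
                          self.auc, self.n_evaluated],
            }
        )


def confusion_metrics(calls, truth) -> ConfusionMetrics:
    """Standard binary confusion metrics with sensitive (+1) as positive class.

    ``calls`` and ``truth`` are vectors in {-1, +1}. If truth lacks a class,
    the rates conditioned on that class are NaN rather than an error.
    """
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if calls.size != truth.size:
        raise ValueError("calls and truth must have equal length")
    if calls.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((calls == 1) & (truth == 1)))
    tn = int(np.sum((calls == -1) & (truth == -1)))
    fp = int(np.sum((calls == 1) & (truth == -1)))
    fn = int(np.sum((calls == -1) & (truth == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    tpr = tp / n_pos if n_pos else math.nan
    tnr = tn / n_neg if n_neg else math.nan
    fpr = fp / n_neg if n_neg else math.nan
    fnr = fn / n_pos if n_pos else math.nan
    if n_pos == 0 or n_neg == 0:
        warnings.warn("truth contains a single class; class-conditional rates are NaN")
    return ConfusionMetrics(
        accuracy=(tp + tn) / calls.size,
        sensitivity=tpr,
        specificity=tnr,
        tpr=tpr,
        fpr=fpr,
        tnr=tnr,
        fnr=fnr,
        n=calls.size,
    )


def balanced_accuracy_auc(tpr: float, fpr: float) -> float:
    """Single-operating-point 'AUC': (tpr - fpr + 1) / 2 == (tpr + tnr) / 2."""
    if not (0 <= tpr <= 1 and 0 <= fpr <= 1):
        raise ValueError("rates must lie in [0, 1]")
    return (tpr - fpr + 1) / 2


def roc_auc(scores, truth) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC curve and its trapezoidal area.

    Returns ``(points, auc)`` where points is an (n, 2) array of (fpr, tpr)
    running monotonically from (0, 0) to (1, 1). Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if np.unique(truth).size < 2:
        raise ValueError("ROC requires both classes in truth")
    fpr, tpr, _ = roc_curve(truth, scores, pos_label=1, drop_intermediate=False)
    auc = float(roc_auc_score(truth, scores))
    return np.column_stack([fpr, tpr]), auc


def calls_from_scores(scores) -> np.ndarray:
    """Responder (+1) iff score strictly positive; 0 is a non-responder."""
    return np.where(np.asarray(scores, dtype=float) > 0, 1, -1)


def loocv(
    X: pd.DataFrame,
    y,
    C: float = 1.0,
    sample_ids=None,
    standardize: bool = True,
) -> EvaluationReport:
    """Leave-one-out cross-validation over the given (already selected) probe set.

    Each sample is held out in turn, the SVM refit on the rest, and the
    held-out sample scored. Folds whose training set degenerates to one class
    are flagged, excluded and counted out of ``n_evaluated``.
    """
    y = np.asarray(y, dtype=int)
    if X.shape[1] != y.size:
        raise ValueError("y must align with the sample columns of X")
    if np.sum(y == 1) < 2 or np.sum(y == -1) < 2:
        raise ValueError("LOOCV requires at least 2 samples per class")
    if sample_ids is None:
        sample_ids = list(map(str, X.columns))

    scores, kept_truth, kept_ids = [], [], []
    for i in range(y.size):
        rest = np.ones(y.size, dtype=bool)
        rest[i] = False
        if np.unique(y[rest]).size < 2:
            warnings.warn(f"LOOCV fold {i}: one-class training set, fold excluded")
            continue
        model = svm.train(X.iloc[:, rest], y[rest], C=C, standardize=standardize)
        scores.append(float(svm.decision_scores(model, X.iloc[:, [i]])[0]))
        kept_truth.append(y[i])
        kept_ids.append(sample_ids[i])

    scores = np.array(scores)
    kept_truth = np.array(kept_truth, dtype=int)
    calls = calls_from_scores(scores)
    cm = confusion_metrics(calls, kept_truth)
    points, auc = roc_auc(scores, kept_truth)
    return EvaluationReport(
        accuracy=cm.accuracy,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        auc=auc,
        roc_points=points,
        n_evaluated=int(scores.size),
        scores=scores,
        calls=calls,
        sample_ids=tuple(kept_ids),
    )


def quadrant_accuracy(scores, neg_log_gi50) -> float:
    """Concordance between predicted sign and response side of the cohort mean.

    The observed class is sign(neg_log_gi50 - mean); samples exactly at the
    mean are excluded. Matches the quadrant reading of a score vs -log(GI50)
    scatter: concordant points fall in the upper-right or lower-left quadrant.
    """
    scores = np.asarray(scores, dtype=float)
    nlg = np.asarray(neg_log_gi50, dtype=float)
    if scores.size != nlg.size:
        raise ValueError("scores and neg_log_gi50 must have equal length")
    observed = np.sign(nlg - nlg.mean())
    keep = observed != 0
    if not keep.any():
        raise ValueError("all samples lie exactly at the mean response")
    return float(np.mean(np.sign(scores[keep]) == observed[keep]))


def response_rate(results) -> float:
    """Fraction of a cohort predicted to respond (score strictly > 0)."""
    if len(results) == 0:
        raise ValueError("empty prediction cohort")
    scores = np.array(
        [r.score if isinstance(r, svm.PredictionResult) else float(r) for r in results]
    )
    return float(np.mean(scores > 0))


def rate_regression(predicted, observed) -> tuple[float, float, float]:
    """OLS of observed on predicted response rates: (slope, intercept, r_squared)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size or predicted.size < 3:
        raise ValueError("need at least 3 aligned (predicted, observed) points")
    if np.allclose(predicted, predicted[0]):
        raise ValueError("zero variance in predicted rates")
    fit = stats.linregress(predicted, observed)
    r2 = 0.0 if np.allclose(observed, observed[0]) else float(fit.rvalue**2)
    return float(fit.slope), float(fit.intercept), r2
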