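"""Soft-margin linear SVM training, scoring and weight ranking.

The classifier separates sensitive (+1) from resistant (-1) expression
profiles with a maximum-margin hyperplane w.x + b = 0, minimizing
(1/2)||w||^2 + C * sum(hinge). Features are standardized inside training
(center/spread learned on the training samples only) and the standardization
is stored in the model, so a single query sample can be scored without any
cohort context. Orientation is fixed semantically: positive score means
predicted sensitive (responder); a score of exactly 0 is a non-responder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearModel:
    """Trained linear classifier: weights, bias and per-feature standardization."""

    probe_ids: tuple[str, ...]
    w: np.ndarray = field(repr=False)
    b: float = 0.0
    center: np.ndarray = field(default=None, repr=False)
    spread: np.ndarray = field(default=None, repr=False)
    C: float = 1.0
    positive_class: int = 1
    drug: str = ""
    fingerprint: str = ""

    def __post_init__(self):
        n = len(self.probe_ids)
        w = np.asarray(self.w, dtype=float)
        center = np.zeros(n) if self.center is None else np.asarray(self.center, dtype=float)
        spread = np.ones(n) if self.spread is None else np.asarray(self.spread, dtype=float)
        if not (w.size == center.size == spread.size == n):
            raise ValueError("probe_ids, w, center and spread must have equal length")
        if not (np.isfinite(w).all() and np.isfinite(center).all() and np.isfinite(spread).all()):
            raise ValueError("model parameters must be finite")
        if np.any(spread <= 0):
            raise ValueError("scale spread must be positive")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "spread", spread)
        object.__setattr__(self, "b", float(self.b))

    def __eq__(self, other):
        if not isinstance(other, LinearModel):
            return NotImplemented
        return (
            self.probe_ids == other.probe_ids
            and np.array_equal(self.w, other.w)
            and self.b == other.b
            and np.array_equal(self.center, other.center)
            and np.array_equal(self.spread, other.spread)
            and self.C == other.C
            and self.positive_class == other.positive_class
            and self.drug == other.drug
            and self.fingerprint == other.fingerprint
        )


@dataclass(frozen=True)
class PredictionResult:
    """Per-sample decision-function score and binary responder call."""

    sample_id: str
    score: float

    @property
    def call(self) -> str:
        return "responder" if self.score > 0 else "non-responder"

    @property
    def is_responder(self) -> bool:
        return self.score > 0


def train(
    X: pd.DataFrame,
    y,
    C: float = 1.0,
    standardize: bool = True,
    drug: str = "",
    fingerprint: str = "",
) -> LinearModel:
    """Fit the soft-margin linear SVM on labeled expression profiles.

    Parameters
    ----------
    X : DataFrame, probes x samples
        Expression restricted to the determinate (labeled) samples.
    y : array of {-1, +1} aligned with X's columns.
    C : soft-margin penalty.
    standardize : learn per-feature center (mean) and spread (SD) on the
        training samples and fit in standardized space; constant features get
        spread 1 (their weight carries no information either way).

    Deterministic given (X, y, C).
    """
    y = np.asarray(y, dtype=int)
    if X.shape[1] != y.size:
        raise ValueError("y must align with the sample columns of X")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise ValueError(f"training labels must contain both classes -1 and +1, got {classes}")
    if C <= 0:
        raise ValueError("C must be positive")

    Xt = X.to_numpy(dtype=float).T  # samples x features
    _warn_on_conflicting_duplicates(Xt, y)
    if standardize:
        center = Xt.mean(axis=0)
        spread = Xt.std(axis=0)
        spread = np.where(spread > 0, spread, 1.0)
    else:
        center = np.zeros(Xt.shape[1])
        spread = np.ones(Xt.shape[1])
    Z = (Xt - center) / spread

    # tight dual tolerance: weights feed the RFE ranking and analytic checks
    svc = SVC(kernel="linear", C=C, tol=1e-6)
    svc.fit(Z, y)
    # sklearn orders classes [-1, +1]; decision_function > 0 predicts +1
    # (sensitive), which is exactly the orientation we want.
    w = svc.coef_.ravel().astype(float)
    b = float(svc.intercept_[0])
    return LinearModel(
        probe_ids=tuple(str(p) for p in X.index),
        w=w,
        b=b,
        center=center,
        spread=spread,
        C=float(C),
        drug=drug,
        fingerprint=fingerprint,
    )


def _warn_on_conflicting_duplicates(Xt: np.ndarray, y: np.ndarray) -> None:
    seen: dict[bytes, int] = {}
    for i in range(Xt.shape[0]):
        key = Xt[i].tobytes()
        if key in seen and y[seen[key]] != y[i]:
            warnings.warn("duplicate training samples with conflicting labels")
            return
        seen.setdefault(key, i)


def decision_scores(model: LinearModel, X: pd.DataFrame) -> np.ndarray:
    """Decision-function values w.x_std + b for each sample column of X.

    X must contain every model probe (rows); extra probes are ignored.
    """
    missing = [p for p in model.probe_ids if p not in X.index]
    if missing:
        raise KeyError(f"query is missing {len(missing)} model probes: {missing[:10]}")
    sub = X.loc[list(model.probe_ids)].to_numpy(dtype=float).T
    Z = (sub - model.center) / model.spread
    return Z @ model.w + model.b


def prediction_score(model: LinearModel, x, sample_id: str = "query") -> PredictionResult:
    """Score a single probe-aligned expression vector.

    ``x`` may be a pandas Series indexed by probe ID (missing probes raise,
    listing the missing IDs) or a bare vector already aligned with
    ``model.probe_ids``.
    """
    if isinstance(x, pd.Series):
        frame = x.to_frame(name=sample_id)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.size != len(model.probe_ids):
            raise ValueError(f"expected {len(model.probe_ids)} values, got {arr.size}")
        frame = pd.DataFrame({sample_id: arr}, index=list(model.probe_ids))
    score = float(decision_scores(model, frame)[0])
    return PredictionResult(sample_id=sample_id, score=score)


def feature_weights(model: LinearModel) -> list[tuple[str, float]]:
    """(probe_id, weight) pairs sorted by descending |weight|, ties by probe ID."""
    pairs = list(zip(model.probe_ids, model.w))
    return sorted(pairs, key=lambda pw: (-abs(pw[1]), pw[0]))
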