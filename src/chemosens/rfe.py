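"""Recursive feature elimination driven by linear-SVM weight magnitudes.

Starting from all probes, the schedule removes the 100 lowest-|weight|
features per round until 100 remain (with a shortened final block when the
start count is not a multiple of 100 above the boundary), then one feature at
a time down to a floor of 10. Validation accuracy on a held-out stratified
split is recorded at every step; the selected model is the one with maximal
accuracy, ties broken toward the fewest features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import svm

logger = logging.getLogger(__name__)

FEATURE_FLOOR = 10
BLOCK_SIZE = 100
ONE_AT_A_TIME_FROM = 100


@dataclass(frozen=True)
class RFEStep:
    n_features: int
    accuracy: float
    probe_ids: tuple[str, ...] = field(repr=False)


@dataclass(frozen=True)
class RFETrace:
    """Sequence of (feature count, validation accuracy, retained set) steps."""

    steps: tuple[RFEStep, ...]
    selected_step: int

    @property
    def selected(self) -> RFEStep:
        return self.steps[self.selected_step]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "n_features": [s.n_features for s in self.steps],
                "accuracy": [s.accuracy for s in self.steps],
                "selected": [i == self.selected_step for i in range(len(self.steps))],
            }
        )

    def retained_at(self, n_features: int) -> tuple[str, ...]:
        """Retained probe set at the step with exactly ``n_features`` features.

        This is the top-``n_features`` slice of the elimination ranking, the
        natural measure of how well the RFE ordering concentrates informative
        probes; raises if the schedule never visited that count.
        """
        for s in self.steps:
            if s.n_features == n_features:
                return s.probe_ids
        raise KeyError(f"no RFE step with {n_features} features")


def split_train_validation(sample_ids, y, fraction: float = 0.75, seed: int = 0):
    """Deterministic stratified split into training and validation sample IDs.

    Each class is shuffled with its own seeded generator and split so that both
    partitions keep at least one sample of each class (rounding is clipped).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    sample_ids = np.asarray(sample_ids)
    y = np.asarray(y, dtype=int)
    if sample_ids.size != y.size:
        raise ValueError("sample_ids and y must align")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has {idx.size} samples; need at least 2 to split")
        perm = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:])
    train_idx = np.sort(np.array(train_idx))
    val_idx = np.sort(np.array(val_idx))
    return sample_ids[train_idx].tolist(), sample_ids[val_idx].tolist()


def rfe_schedule(n_start: int, floor: int = FEATURE_FLOOR, block: int = BLOCK_SIZE) -> list[int]:
    """Feature counts visited by the elimination schedule, descending.

    From ``n_start`` remove ``block`` features per round while at least
    ``2*block`` remain, then a shortened block landing exactly on ``block``;
    from there remove one at a time down to ``floor``. Starts at or below
    ``block`` go one at a time from the start.
    """
    if n_start < floor:
        raise ValueError(f"a model requires a minimum of {floor} probes; got {n_start}")
    counts = [n_start]
    n = n_start
    boundary = block
    while n > boundary:
        n -= min(block, n - boundary)
        counts.append(n)
    while n > floor:
        n -= 1
        counts.append(n)
    return counts


def _validation_accuracy(model: svm.LinearModel, X_val: pd.DataFrame, y_val: np.ndarray) -> float:
    scores = svm.decision_scores(model, X_val)
    pred = np.where(scores > 0, 1, -1)
    return float(np.mean(pred == y_val))


def _elimination_order(model: svm.LinearModel) -> list[str]:
    """Probes ordered from least to most relevant: ascending |w|, ties dropping
    lexicographically larger probe IDs first."""
    ranked = svm.feature_weights(model)  # descending |w|, ties lexicographic asc
    return [pid for pid, _ in reversed(ranked)]


def run_rfe(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    C: float = 1.0,
    schedule: list[int] | None = None,
    floor: int = FEATURE_FLOOR,
    block: int = BLOCK_SIZE,
) -> RFETrace:
    """Run the elimination schedule, recording validation accuracy per step.

    At each step a fresh SVM (with re-learned standardization) is trained on
    the currently retained probes; the lowest-|weight| probes are dropped to
    reach the next count. Selection: maximal validation accuracy, ties broken
    toward the fewest features.
    """
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if not X_train.index.equals(X_val.index):
        missing = X_train.index.difference(X_val.index)
        if len(missing):
            raise ValueError(f"validation matrix lacks {len(missing)} training probes")
        X_val = X_val.loc[X_train.index]
    if schedule is None:
        schedule = rfe_schedule(X_train.shape[0], floor=floor, block=block)
    elif schedule[0] != X_train.shape[0]:
        raise ValueError("schedule must start at the current feature count")

    current = list(map(str, X_train.index))
    steps: list[RFEStep] = []
    for step_i, target in enumerate(schedule):
        if len(current) != target:
            raise RuntimeError(f"internal schedule mismatch at step {step_i}")
        try:
            model = svm.train(X_train.loc[current], y_train, C=C)
        except ValueError as exc:
            raise ValueError(f"RFE step {step_i} ({target} features): {exc}") from exc
        acc = _validation_accuracy(model, X_val.loc[current], y_val)
        steps.append(RFEStep(target, acc, tuple(current)))
        logger.debug("RFE step %d: %d features, validation accuracy %.3f", step_i, target, acc)
        if step_i + 1 < len(schedule):
            n_drop = target - schedule[step_i + 1]
            drop = set(_elimination_order(model)[:n_drop])
            current = [p for p in current if p not in drop]

    best = max(range(len(steps)), key=lambda i: (steps[i].accuracy, -steps[i].n_features))
    return RFETrace(tuple(steps), best)


def finalize_model(
    trace: RFETrace,
    X_train: pd.DataFrame,
    y_train,
    C: float = 1.0,
    drug: str = "",
    fingerprint: str = "",
) -> svm.LinearModel:
    """Refit on the training partition restricted to the selected probe set."""
    probes = list(trace.selected.probe_ids)
    return svm.train(
        X_train.loc[probes], np.asarray(y_train, dtype=int), C=C,
        drug=drug, fingerprint=fingerprint,
    )


def ranking_recovery(trace: RFETrace, target_probes, k: int | None = None) -> float:
    """Fraction of ``target_probes`` present in the retained set of size k.

    Defaults k to the number of target probes, i.e. recovery of the planted
    set within the top-k of the elimination ranking.
    """
    targets = set(map(str, target_probes))
    if k is None:
        k = len(targets)
    sizes = [s.n_features for s in trace.steps]
    feasible = [n for n in sizes if n >= k]
    at = min(feasible) if feasible else max(sizes)
    retained = set(trace.retained_at(at))
    return len(targets & retained) / len(targets)
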