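"""GI50 transformation and three-way response bifurcation.

Cell-line drug sensitivity is summarized by GI50, the molar concentration
inhibiting growth by 50%. Working on -log10(GI50), higher values mean more
sensitive. Samples are labeled sensitive (+1) above mean + 0.5*SD, resistant
(-1) below mean - 0.5*SD, and indeterminate (0) inside the band; indeterminate
samples are excluded from learning but not from prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SENSITIVE, INDETERMINATE, RESISTANT = 1, 0, -1


def neg_log_transform(gi50):
    """-log10 of a positive GI50 (molar). Higher output = more sensitive.

    Accepts scalars or arrays; non-positive values raise.
    """
    arr = np.asarray(gi50, dtype=float)
    if np.any(arr <= 0) or not np.isfinite(arr).all():
        raise ValueError("GI50 values must be positive and finite for the log transform")
    out = -np.log10(arr)
    return float(out) if np.isscalar(gi50) or arr.ndim == 0 else out


@dataclass(frozen=True)
class LabelVector:
    """Bifurcated response labels with the statistics that defined them."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray = field(repr=False)  # int8 in {-1, 0, +1}
    neg_log_gi50: np.ndarray = field(repr=False)
    mean: float
    sd: float

    @property
    def n_sensitive(self) -> int:
        return int(np.sum(self.labels == SENSITIVE))

    @property
    def n_resistant(self) -> int:
        return int(np.sum(self.labels == RESISTANT))

    @property
    def n_indeterminate(self) -> int:
        return int(np.sum(self.labels == INDETERMINATE))


def bifurcate(neg_log_gi50, sample_ids=None, band_sd: float = 0.5) -> LabelVector:
    """Label each sample sensitive/indeterminate/resistant around the cohort mean.

    Thresholds are mean +/- band_sd * SD, with the sample (n-1) standard
    deviation. Strict inequalities: values exactly on a threshold are
    indeterminate. A zero-variance input yields all-indeterminate labels and
    a warning. Requires at least 3 finite values.
    """
    values = np.asarray(neg_log_gi50, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("bifurcation requires a 1-D vector of at least 3 values")
    if not np.isfinite(values).all():
        raise ValueError("bifurcation input must be finite (exclude missing GI50 first)")
    if sample_ids is None:
        sample_ids = tuple(f"S{i}" for i in range(values.size))
    sample_ids = tuple(str(s) for s in sample_ids)
    if len(sample_ids) != values.size:
        raise ValueError("sample_ids length mismatch")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    labels = np.zeros(values.size, dtype=np.int8)
    if sd == 0.0:
        warnings.warn("zero variance in response values: all samples indeterminate")
    else:
        labels[values > mean + band_sd * sd] = SENSITIVE
        labels[values < mean - band_sd * sd] = RESISTANT
    return LabelVector(sample_ids, labels, values, mean, sd)


def learning_mask(labels: LabelVector) -> np.ndarray:
    """Boolean mask of samples usable for learning (label != 0), order preserved.

    Raises if either retained class has fewer than 2 samples, because an SVM
    cannot be trained (or meaningfully validated) on it. No mask is applied at
    prediction time: test samples come from the full distribution.
    """
    mask = labels.labels != INDETERMINATE
    n_pos = int(np.sum(labels.labels == SENSITIVE))
    n_neg = int(np.sum(labels.labels == RESISTANT))
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"too few determinate samples to learn from (sensitive={n_pos}, resistant={n_neg})"
        )
    logger.info(
        "learning mask retains %d/%d samples (%d sensitive, %d resistant)",
        int(mask.sum()), mask.size, n_pos, n_neg,
    )
    return mask
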