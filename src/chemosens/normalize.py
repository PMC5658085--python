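"""One-by-one quantile normalization against a fixed reference distribution.

Each query array is normalized independently against a target distribution
built once from the reference (training) expression matrix, so a sample's
normalized values never depend on which other samples arrive in the same
batch — the property that makes the pipeline usable one patient at a time.

The default target is the standard quantile-normalization target: the
rank-wise mean of the sorted reference arrays. An alternative target built
from sorted per-probe means is available as ``mode="probe-mean"`` for
comparison, but is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Target distribution for single-sample quantile normalization.

    ``quantiles[k]`` is the value every query's (k+1)-th smallest intensity is
    mapped to. ``probe_ids`` records the feature space the reference was built
    on; its length equals ``len(quantiles)``.
    """

    probe_ids: tuple[str, ...]
    quantiles: np.ndarray = field(repr=False)

    def __post_init__(self):
        q = np.asarray(self.quantiles, dtype=float)
        if len(self.probe_ids) != q.size:
            raise ValueError("probe_ids and quantiles must have equal length")
        if q.size == 0:
            raise ValueError("empty reference distribution")
        if not np.isfinite(q).all():
            raise ValueError("reference quantiles must be finite")
        if np.any(np.diff(q) < 0):
            raise ValueError("reference quantiles must be non-decreasing")
        object.__setattr__(self, "quantiles", q)


def build_reference(reference: pd.DataFrame, mode: str = "rank-mean") -> ReferenceDistribution:
    """Build the normalization target from a probe x sample reference matrix.

    mode="rank-mean" (default): quantiles[k] = mean over arrays of each
    array's k-th smallest value (standard quantile normalization).
    mode="probe-mean": quantiles = sorted vector of per-probe mean intensities.
    """
    if reference.size == 0:
        raise ValueError("cannot build a reference distribution from an empty matrix")
    values = reference.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("reference matrix contains non-finite values")
    if mode == "rank-mean":
        quantiles = np.sort(values, axis=0).mean(axis=1)
    elif mode == "probe-mean":
        quantiles = np.sort(values.mean(axis=1))
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return ReferenceDistribution(tuple(str(p) for p in reference.index), quantiles)


def normalize_sample(query: np.ndarray, ref: ReferenceDistribution) -> np.ndarray:
    """Map one query vector onto the reference quantiles by rank.

    ``out[i]`` is the reference quantile at the rank of ``query[i]`` within the
    query. Tied query values all receive the mean of the reference quantiles at
    the tied ranks, so the mapping is deterministic and order-free. For a
    tie-free query the output is an exact permutation of the quantiles.
    """
    q = np.asarray(query, dtype=float)
    if q.ndim != 1:
        raise ValueError("query must be a 1-D vector")
    if q.size != ref.quantiles.size:
        raise ValueError(f"query length {q.size} != reference length {ref.quantiles.size}")
    if not np.isfinite(q).all():
        raise ValueError("query contains non-finite values")
    order = np.argsort(q, kind="stable")
    out = np.empty(q.size, dtype=float)
    out[order] = ref.quantiles
    # ties: average the quantiles assigned within each tied group
    _, inverse, counts = np.unique(q, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        sums = np.bincount(inverse, weights=out)
        out = (sums / counts)[inverse]
    return out


def normalize_cohort(queries: pd.DataFrame, ref: ReferenceDistribution) -> pd.DataFrame:
    """Normalize every column of a query cohort independently ("one-by-one").

    Probes are intersected with the reference feature space, keeping the
    reference order. Query probes absent from the reference are dropped with a
    logged count; if reference probes are missing from the query, the target
    quantiles are rebuilt on the intersection by interpolating the reference
    distribution at the reduced number of ranks.
    """
    ref_probes = list(ref.probe_ids)
    query_set = set(queries.index)
    common = [p for p in ref_probes if p in query_set]
    if not common:
        raise ValueError("no probes shared between query and reference")
    dropped = len(queries.index) - len(common)
    if dropped:
        logger.warning("dropping %d query probes absent from the reference", dropped)
    if len(common) < len(ref_probes):
        logger.warning(
            "query covers %d of %d reference probes; rebuilding target on the intersection",
            len(common), len(ref_probes),
        )
        grid_full = np.linspace(0.0, 1.0, len(ref_probes))
        grid_sub = np.linspace(0.0, 1.0, len(common))
        sub_ref = ReferenceDistribution(
            tuple(common), np.interp(grid_sub, grid_full, ref.quantiles)
        )
    else:
        sub_ref = ref
    sub = queries.loc[common]
    out = np.column_stack([normalize_sample(sub[c].to_numpy(), sub_ref) for c in sub.columns])
    return pd.DataFrame(out, index=common, columns=sub.columns)


def write_reference(ref: ReferenceDistribution, path) -> None:
    """Cache a reference distribution as TSV (probe_id, quantile)."""
    with open(path, "w") as fh:
        fh.write("probe_id\tquantile\n")
        for pid, q in zip(ref.probe_ids, ref.quantiles):
            fh.write(f"{pid}\t{float(q)!r}\n")


def read_reference(path) -> ReferenceDistribution:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return ReferenceDistribution(tuple(df["probe_id"]), df["quantile"].to_numpy(dtype=float))
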