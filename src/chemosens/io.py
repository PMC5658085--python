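"""Text-format readers and writers for expression matrices, response tables,
trained models and prediction outputs.

All formats are plain text so that models and intermediate artifacts stay
diff-able and portable. Expression matrices are probe-major on disk (rows are
probes, columns are samples); a ``transpose`` flag accommodates sample-major
files. Model files are a structured key-value document storing weights to full
float precision, so ``read_model(write_model(m)) == m`` bit for bit.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .svm import LinearModel

MODEL_FORMAT_VERSION = 1


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix violates the format contract."""


class ModelFormatError(ValueError):
    """Raised when a model file is malformed, truncated or version-mismatched."""


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise MatrixFormatError(f"{path}: could not detect tab or comma delimiter in header")


def read_expression_matrix(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read a probe x sample expression matrix from delimited text.

    First row holds sample IDs, first column probe IDs. The delimiter (tab or
    comma) is auto-detected. Duplicate IDs, non-numeric cells and missing
    values are rejected with the offending row/column named.

    Parameters
    ----------
    path : str or Path
    transpose : bool
        If True the file is sample-major (rows are samples) and the result is
        transposed back to probe x sample.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    return validate_expression_matrix(df, name=str(path))


def validate_expression_matrix(df: pd.DataFrame, name: str = "expression matrix") -> pd.DataFrame:
    """Enforce the ExpressionMatrix invariants: unique IDs, all-finite numeric values."""
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{name}: empty matrix")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"{name}: duplicate probe IDs {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise MatrixFormatError(f"{name}: duplicate sample IDs {dups}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = [
            (str(df.index[i]), str(df.columns[j]))
            for i in range(df.shape[0])
            for j in range(df.shape[1])
            if not _is_number(df.iat[i, j])
        ]
        raise MatrixFormatError(f"{name}: non-numeric cells at (probe, sample) {bad[:5]}") from exc
    if not np.isfinite(values.to_numpy()).all():
        mask = ~np.isfinite(values.to_numpy())
        i, j = np.argwhere(mask)[0]
        raise MatrixFormatError(
            f"{name}: non-finite value at probe {values.index[i]!r}, sample {values.columns[j]!r}"
        )
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    return values


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a probe x sample matrix as TSV (probe-major)."""
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_response_table(path: str | Path) -> pd.DataFrame:
    """Read a GI50 response table, returning a sample x drug DataFrame (molar).

    Two layouts are accepted: long format with exactly the columns
    ``sample``/``drug``/``gi50`` (any capitalization), or wide format with
    sample IDs in the first column and one column per drug. Missing entries
    (blank cells in wide format) are allowed and stay NaN; present entries
    must be positive.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    cols = [c.strip().lower() for c in df.columns]
    if len(df.columns) == 3 and set(cols) == {"sample", "drug", "gi50"}:
        df.columns = cols
        wide = df.pivot_table(index="sample", columns="drug", values="gi50", aggfunc="first")
        wide.index = wide.index.astype(str)
    else:
        wide = df.set_index(df.columns[0])
        wide.index = wide.index.astype(str)
        wide = wide.astype(float)
    if wide.index.has_duplicates:
        dups = wide.index[wide.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"{path}: duplicate sample IDs {dups}")
    present = wide.to_numpy()
    bad = (present <= 0) & np.isfinite(present)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixFormatError(
            f"{path}: non-positive GI50 for sample {wide.index[i]!r}, drug {wide.columns[j]!r}"
        )
    wide.columns = [str(c) for c in wide.columns]
    wide.index.name = "sample"
    return wide


def write_response_table(wide: pd.DataFrame, path: str | Path) -> None:
    """Write a sample x drug GI50 table in long format (sample, drug, gi50)."""
    long = wide.stack().rename("gi50").reset_index()
    long.columns = ["sample", "drug", "gi50"]
    long.to_csv(path, sep="\t", index=False)


def write_model(model: LinearModel, path: str | Path) -> None:
    """Serialize a trained linear model as a human-readable key-value document.

    Floats are written with ``repr`` so the round trip is exact for float64.
    """
    lines = [
        "# chemosens linear model",
        f"format_version: {MODEL_FORMAT_VERSION}",
        f"drug: {model.drug}",
        f"C: {float(model.C)!r}",
        f"bias: {float(model.b)!r}",
        f"positive_class: {model.positive_class}",
        f"config_fingerprint: {model.fingerprint}",
        f"n_features: {len(model.probe_ids)}",
        "probe_id\tweight\tcenter\tspread",
    ]
    for pid, w, c, s in zip(model.probe_ids, model.w, model.center, model.spread):
        lines.append(f"{pid}\t{float(w)!r}\t{float(c)!r}\t{float(s)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> LinearModel:
    """Load a model written by :func:`write_model`; truncated or mismatched files raise."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header: dict[str, str] = {}
    rows: list[str] = []
    for ln in lines:
        if "\t" in ln:
            rows.append(ln)
        elif ": " in ln or ln.endswith(":"):
            key, _, val = ln.partition(":")
            header[key.strip()] = val.strip()
        else:
            raise ModelFormatError(f"{path}: unparseable line {ln!r}")
    required = {"format_version", "C", "bias", "positive_class", "n_features"}
    missing = required - header.keys()
    if missing:
        raise ModelFormatError(f"{path}: missing fields {sorted(missing)}")
    if int(header["format_version"]) != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {header['format_version']} != {MODEL_FORMAT_VERSION}"
        )
    n = int(header["n_features"])
    body = rows[1:] if rows and rows[0].startswith("probe_id") else rows
    if len(body) != n:
        raise ModelFormatError(f"{path}: expected {n} feature rows, found {len(body)} (truncated?)")
    probe_ids, w, center, spread = [], [], [], []
    for ln in body:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ModelFormatError(f"{path}: malformed feature row {ln!r}")
        probe_ids.append(parts[0])
        w.append(float(parts[1]))
        center.append(float(parts[2]))
        spread.append(float(parts[3]))
    return LinearModel(
        probe_ids=tuple(probe_ids),
        w=np.array(w, dtype=float),
        b=float(header["bias"]),
        center=np.array(center, dtype=float),
        spread=np.array(spread, dtype=float),
        C=float(header["C"]),
        positive_class=int(header["positive_class"]),
        drug=header.get("drug", ""),
        fingerprint=header.get("config_fingerprint", ""),
    )


def write_predictions(df: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table (sample_id, drug, score, call) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
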