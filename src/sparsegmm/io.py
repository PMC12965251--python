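"""Readers and writers for matrices, labels, and run reports.

Matrices are oriented features x observations everywhere.  Dense CSV/TSV
(with an optional header row and optional row-name column, both
auto-detected) and MatrixMarket MTX are supported.  Label files hold one
1-based integer per line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from numpy.typing import NDArray

from .core_model import DataMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_report",
    "save_trace",
]


def _read_dense(path: Path, sep: str) -> DataMatrix:
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = head.iloc[0].apply(
        lambda v: isinstance(v, str) and not _is_number(v)
    ).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    obs_names = [str(c) for c in df.columns] if has_header else None
    feat_names = None
    first = df.iloc[:, 0]
    if first.dtype == object and not first.map(_is_number).all():
        feat_names = [str(v) for v in first]
        df = df.iloc[:, 1:]
        if obs_names is not None:
            obs_names = obs_names[1:]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    return DataMatrix(values, feature_names=feat_names, observation_names=obs_names)


def _is_number(v: Any) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_matrix(path: str | Path, transpose: bool = False) -> DataMatrix:
    """Load a features x observations matrix from CSV, TSV, or MTX.

    ``transpose=True`` flips an observations x features file (e.g. a
    cells x genes export) into the package's orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        dm = DataMatrix(values)
    elif suffix in (".tsv", ".txt"):
        dm = _read_dense(path, sep="\t")
    else:
        dm = _read_dense(path, sep=",")
    if transpose:
        dm = DataMatrix(
            dm.values.T,
            feature_names=dm.observation_names,
            observation_names=dm.feature_names,
        )
    return dm


def write_matrix(path: str | Path, matrix: DataMatrix | NDArray) -> None:
    """Write a matrix as CSV (features x observations, no header)."""
    values = matrix.values if isinstance(matrix, DataMatrix) else np.asarray(matrix)
    np.savetxt(path, values, delimiter=",", fmt="%.10g")


def read_labels(path: str | Path) -> NDArray[np.int_]:
    """Read 1-based integer labels, one per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels = np.loadtxt(path, dtype=int, ndmin=1)
    if labels.ndim != 1:
        raise ValueError("label files must hold one integer per line")
    if labels.min() < 1:
        raise ValueError("labels must be 1-based positive integers")
    return labels


def write_labels(path: str | Path, labels: NDArray[np.int_]) -> None:
    """Write 1-based integer labels, one per line."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and labels.min() < 1:
        raise ValueError("labels must be 1-based positive integers")
    np.savetxt(path, labels, fmt="%d")


def write_report(path: str | Path, report: dict[str, Any]) -> None:
    """Serialize a JSON run report (seed, config, summary statistics)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def save_trace(out_dir: str | Path, trace) -> None:
    """Serialize a trace: label samples as integer TSV, scalars as CSV.

    Writes ``trace_z.tsv`` (one kept sample per row) and
    ``trace_scalars.csv`` with per-iteration K, log joint, theta, and the
    number of active features.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "trace_z.tsv", trace.z, fmt="%d", delimiter="\t")
    scalars = np.column_stack([trace.K, trace.log_joint, trace.theta, trace.n_xi])
    np.savetxt(
        out_dir / "trace_scalars.csv",
        scalars,
        delimiter=",",
        header="K,log_joint,theta,n_xi",
        comments="",
        fmt="%.10g",
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
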