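"""Data container and delimited-text I/O.

The package operates on a plain numeric matrix ``X`` (n samples in rows,
p variables in columns) with a binary group-label vector ``Y`` whose values
are coded ``{1, 2}``.  Arbitrary two-valued labels in input files are mapped
to ``{1, 2}`` by sorted order; the mapping is logged.  Missing values are a
hard error -- rows with missing entries are rejected, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mrrmrr")

#: Default seed used by every randomized operation when none is supplied.
DEFAULT_SEED = 42


class DataError(ValueError):
    """Raised when an input file or matrix violates the data contract."""


@dataclass
class DataMatrix:
    """An n x p numeric matrix with binary group labels.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric observations, samples in rows.
    Y : ndarray of shape (n,)
        Group labels, values in ``{1, 2}``, each present at least twice.
    variable_names : sequence of p unique strings
    sample_ids : sequence of n strings
    metadata : dict
        Free-form sidecar information (e.g. ground-truth informative
        column indices for synthetic data).
    """

    X: np.ndarray
    Y: np.ndarray
    variable_names: Sequence[str] = None
    sample_ids: Sequence[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError("X must be a 2-d matrix")
        self.Y = np.asarray(self.Y)
        n, p = self.X.shape
        if n < 4:
            raise DataError(f"need at least 4 samples, got {n}")
        if p < 1:
            raise DataError("need at least 1 variable")
        if self.Y.shape != (n,):
            raise DataError(f"Y has length {self.Y.shape}, expected ({n},)")
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise DataError(
                f"missing/non-finite value at row {bad[0] + 1}, column {bad[1] + 1}; "
                "rows with missing entries must be removed before loading"
            )
        labels = np.unique(self.Y)
        if not np.array_equal(labels, np.array([1, 2])):
            raise DataError(f"Y must contain exactly the labels 1 and 2, got {labels}")
        counts = [(self.Y == g).sum() for g in (1, 2)]
        if min(counts) < 2:
            raise DataError(
                f"each group needs at least 2 samples for LOOCV with LDA, got {counts}"
            )
        self.Y = self.Y.astype(int)
        if self.variable_names is None:
            self.variable_names = [f"V{j + 1}" for j in range(p)]
        self.variable_names = list(map(str, self.variable_names))
        if len(self.variable_names) != p:
            raise DataError("variable_names length mismatch")
        if len(set(self.variable_names)) != p:
            raise DataError("variable_names must be unique")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        self.sample_ids = list(map(str, self.sample_ids))
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _coerce_numeric(frame: pd.DataFrame) -> np.ndarray:
    """Convert a DataFrame to a float matrix, naming the offending cell."""
    out = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        raw_na = frame[col].isna()
        bad = converted.isna() & ~raw_na
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise DataError(
                f"non-numeric value {frame[col].iloc[i]!r} at row {i + 1}, "
                f"column {j + 1} ({col!r})"
            )
        out[:, j] = converted.to_numpy()
    return out


def read_matrix(
    path: str | Path,
    label_spec: str | Path,
    delimiter: str = ",",
    samples_in_rows: bool = True,
) -> DataMatrix:
    """Read a delimited numeric matrix plus binary group labels.

    Parameters
    ----------
    path : file path
        CSV/TSV file with a header row.
    label_spec : str or path
        Either the name of the label column inside `path`, or the path of a
        one-column companion file holding one label per sample.
    delimiter : str
        Field separator (``','`` or ``'\\t'``).
    samples_in_rows : bool
        If False the file stores variables in rows and is transposed after
        reading (the label column, if internal, is then a label *row*
        identified by its header in the first column).

    Returns
    -------
    DataMatrix
        Labels are mapped to ``{1, 2}`` by the sorted order of their two
        distinct raw values; the mapping is logged.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if not samples_in_rows:
        frame = frame.T

    labels_raw = None
    label_col = str(label_spec)
    if label_col in frame.columns:
        labels_raw = frame[label_col].to_numpy()
        frame = frame.drop(columns=[label_col])
    else:
        label_path = Path(label_spec)
        if not label_path.exists():
            raise DataError(
                f"label spec {label_spec!r} is neither a column of {path} "
                "nor an existing file"
            )
        lab = pd.read_csv(label_path, sep=delimiter, float_precision="round_trip")
        if lab.shape[1] != 1:
            raise DataError("companion label file must have exactly one column")
        labels_raw = lab.iloc[:, 0].to_numpy()
        if len(labels_raw) != frame.shape[0]:
            raise DataError(
                f"label file has {len(labels_raw)} entries for {frame.shape[0]} samples"
            )

    uniq = sorted(pd.unique(labels_raw), key=str)
    if len(uniq) != 2:
        raise DataError(f"labels must take exactly two distinct values, got {uniq}")
    mapping = {uniq[0]: 1, uniq[1]: 2}
    logger.info("label mapping: %r -> 1, %r -> 2", uniq[0], uniq[1])
    Y = np.array([mapping[v] for v in labels_raw])

    X = _coerce_numeric(frame)
    return DataMatrix(
        X=X,
        Y=Y,
        variable_names=list(frame.columns),
        sample_ids=list(map(str, frame.index)),
        metadata={"label_mapping": {str(k): v for k, v in mapping.items()}},
    )


def write_matrix(data: DataMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a DataMatrix (with a ``group`` label column) back to delimited text."""
    frame = pd.DataFrame(data.X, index=data.sample_ids, columns=data.variable_names)
    frame.insert(0, "group", data.Y)
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def _report_frame(result: Any) -> pd.DataFrame:
    """One row per selected variable, or per gamma for a CV report."""
    if hasattr(result, "per_gamma"):  # CVReport
        return pd.DataFrame(
            [
                {
                    "gamma": rec["gamma"],
                    "sensitivity": rec["sensitivity"],
                    "specificity": rec["specificity"],
                    "accuracy": rec["accuracy"],
                    "selected": ";".join(map(str, rec["selected"])),
                }
                for rec in result.per_gamma
            ]
        )
    # SelectionResult
    rows = []
    for rank, (idx, step) in enumerate(zip(result.selected, result.steps), start=1):
        rows.append(
            {
                "rank": rank,
                "index": idx,
                "name": step.get("name", str(idx)),
                "relevance": step["relevance"],
                "redundancy": step["redundancy"],
                "score": step["score"],
            }
        )
    return pd.DataFrame(rows)


def write_report(result: Any, path: str | Path, format: str = "tabular") -> None:
    """Write a SelectionResult or CVReport to disk.

    ``tabular`` writes a TSV with one row per selected variable (rank, name,
    relevance, redundancy, score) or per gamma (gamma, SE, SP, accuracy);
    ``structured-text`` writes a nested key-value (YAML) document with full
    diagnostics.  Floats are written with 17 significant digits so that a
    read-back reproduces them exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if format == "tabular":
        _report_frame(result).to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "structured-text":
        payload = _to_plain(result)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _to_plain(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy objects to YAML-safe types."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def load_config(path: str | Path) -> dict:
    """Load a key-value configuration file (YAML) mirroring the CLI flags."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError("configuration file must be a mapping of option: value")
    return cfg
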