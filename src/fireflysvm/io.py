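"""Readers and writers: dense CSV, svmlight/libsvm sparse text, and JSON
model documents.

CSV convention: one row per sample, the label in a designated column
(default: last).  Binary label sets are normalized to {-1, +1} with the
mapping recorded ({0,1} maps 1 -> +1).  svmlight files use the standard
``label index:value`` lines with 1-based feature indices, mapped to
0-based columns in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

from .multiclass import OAAModel
from .types import Dataset, SVMModel

__all__ = [
    "read_csv_dataset",
    "write_csv_dataset",
    "read_svmlight",
    "write_svmlight",
    "normalize_binary_labels",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "save_oaa_model",
    "load_oaa_model",
]


def normalize_binary_labels(y: np.ndarray) -> tuple[np.ndarray, dict]:
    """Map a two-valued label vector onto {-1, +1}.

    The larger original value (1 in a {0,1} coding) becomes +1.  Returns
    the mapped labels and the mapping record {original: mapped}.
    """
    values = np.unique(y)
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 label values, got {len(values)}")
    lo, hi = sorted(values.tolist())
    mapping = {lo: -1, hi: 1}
    return np.where(y == hi, 1, -1), mapping


def read_csv_dataset(
    path: str | Path,
    label_column: int | str = -1,
    header: bool = False,
    delimiter: str = ",",
    binary: bool = True,
) -> Dataset:
    """Load a dense CSV into a Dataset.

    ``label_column`` is a 0-based column index (negative allowed) or, with
    ``header=True``, a column name.  With ``binary=True`` a two-valued
    label column is normalized to {-1, +1}.
    """
    try:
        frame = pd.read_csv(
            path, header=0 if header else None, sep=delimiter
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if isinstance(label_column, str):
        if label_column not in frame.columns:
            raise ValueError(f"unknown label column {label_column!r}")
        y_series = frame[label_column]
        X_frame = frame.drop(columns=[label_column])
    else:
        try:
            y_series = frame.iloc[:, label_column]
        except IndexError as exc:
            raise ValueError(f"unknown label column {label_column}") from exc
        X_frame = frame.drop(columns=[frame.columns[label_column]])
    X = X_frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0]) + 1 + int(header)
        raise ValueError(f"non-numeric or missing cell at data line {row} of {path}")
    y = y_series.to_numpy()
    if binary:
        y, _ = normalize_binary_labels(y)
    else:
        y = y.astype(int)
    return Dataset(X, y)


def write_csv_dataset(
    data: Dataset,
    path: str | Path,
    header: bool = False,
    delimiter: str = ",",
) -> None:
    """Write features then the label as the last column."""
    frame = pd.DataFrame(data.X)
    frame["label"] = data.y
    frame.to_csv(
        path, index=False, header=header, sep=delimiter,
        float_format="%.17g",
    )


def read_svmlight(path: str | Path, binary: bool = True) -> Dataset:
    """Load an svmlight/libsvm sparse file (1-based indices on disk map to
    0-based columns in memory)."""
    try:
        X, y = load_svmlight_file(str(path))
    except ValueError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    X = np.asarray(X.todense(), dtype=float)
    if binary:
        y, _ = normalize_binary_labels(y)
    else:
        y = y.astype(int)
    return Dataset(X, y)


def write_svmlight(data: Dataset, path: str | Path) -> None:
    dump_svmlight_file(data.X, data.y, str(path), zero_based=False)


def model_to_dict(model: SVMModel, extra: dict | None = None) -> dict:
    doc = {
        "sv_features": model.sv_features.tolist(),
        "sv_alpha": model.sv_alpha.tolist(),
        "sv_labels": model.sv_labels.tolist(),
        "bias": model.bias,
        "gamma_kernel": model.gamma_kernel,
        "C": model.C,
    }
    if extra:
        doc.update(extra)
    return doc


def model_from_dict(doc: dict) -> SVMModel:
    return SVMModel(
        sv_features=np.asarray(doc["sv_features"], dtype=float),
        sv_alpha=np.asarray(doc["sv_alpha"], dtype=float),
        sv_labels=np.asarray(doc["sv_labels"], dtype=float),
        bias=float(doc["bias"]),
        gamma_kernel=float(doc["gamma_kernel"]),
        C=float(doc["C"]),
    )


def save_model(model: SVMModel, path: str | Path, extra: dict | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, extra), indent=1))


def load_model(path: str | Path) -> SVMModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_oaa_model(model: OAAModel, path: str | Path, extra: dict | None = None) -> None:
    doc = {
        "class_tags": np.asarray(model.class_tags).tolist(),
        "machines": [model_to_dict(m) for m in model.machines],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_oaa_model(path: str | Path) -> OAAModel:
    doc = json.loads(Path(path).read_text())
    return OAAModel(
        class_tags=np.asarray(doc["class_tags"]),
        machines=[model_from_dict(d) for d in doc["machines"]],
    )
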