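"""Delimited-table readers and writers.

Tables are plain CSV/TSV (delimiter auto-detected from the extension).  The
default orientation is samples-in-rows with a designated label column;
microarray-style matrices with genes in rows and samples in columns are
supported through ``genes_in_rows``, in which case the label row is found by
name in the first column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeatureWeights, LabeledDataset
from .exceptions import SchemaError, TableParseError, ValidationError

__all__ = [
    "TableSpec",
    "read_labeled_table",
    "write_dataset",
    "write_weights",
    "read_weights",
]


@dataclass(frozen=True)
class TableSpec:
    """Where and how to read a labeled table."""

    path: str
    delimiter: str | None = None  # auto by extension when None
    label_column: str = "label"
    genes_in_rows: bool = False

    @property
    def sep(self) -> str:
        if self.delimiter is not None:
            return self.delimiter
        ext = os.path.splitext(self.path)[1].lower()
        return "\t" if ext in (".tsv", ".tab", ".txt") else ","


def _coerce_numeric(frame: pd.DataFrame) -> np.ndarray:
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & ~frame.isna()
    bad |= frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise TableParseError(
            f"non-numeric cell {frame.iat[r, c]!r} at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r}"
        )
    return values.to_numpy(dtype=float)


def read_labeled_table(spec: TableSpec) -> LabeledDataset:
    """Parse a delimited table into a :class:`LabeledDataset`.

    Labels are mapped to contiguous integers ``1..c`` in sorted order of the
    original values, which are retained in ``label_names`` for round-tripping.
    """
    frame = pd.read_csv(spec.path, sep=spec.sep)
    if spec.genes_in_rows:
        raw_names = [str(v) for v in frame.iloc[:, 0]]
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
        frame.columns.name = None
    else:
        # pandas silently mangles duplicate header names; check the raw header
        header = pd.read_csv(spec.path, sep=spec.sep, header=None, nrows=1)
        raw_names = [str(v) for v in header.iloc[0]]
    dupes = sorted({n for n in raw_names if raw_names.count(n) > 1})
    if dupes:
        raise SchemaError(f"duplicate feature names: {dupes}")
    if spec.label_column not in frame.columns:
        raise SchemaError(
            f"label column {spec.label_column!r} not found in {spec.path} "
            f"(columns: {list(frame.columns)[:8]}...)"
        )
    labels_raw = frame[spec.label_column]
    features = frame.drop(columns=[spec.label_column])
    names = [str(c) for c in features.columns]
    X = _coerce_numeric(features)
    originals = sorted(pd.unique(labels_raw), key=lambda s: (str(type(s)), s))
    mapping = {orig: i + 1 for i, orig in enumerate(originals)}
    y = labels_raw.map(mapping).to_numpy(dtype=int)
    return LabeledDataset(X, y, tuple(names), label_names=tuple(originals))


def write_dataset(dataset: LabeledDataset, path, label_column: str = "label") -> None:
    """Write a dataset as a delimited table (inverse of ``read_labeled_table``)."""
    sep = TableSpec(path=str(path)).sep
    frame = pd.DataFrame(dataset.features, columns=list(dataset.feature_names))
    if dataset.label_names is not None:
        frame[label_column] = [dataset.label_names[y - 1] for y in dataset.labels]
    else:
        frame[label_column] = dataset.labels
    frame.to_csv(path, sep=sep, index=False)


def write_weights(weights, feature_names, path) -> None:
    """Two-column TSV ``feature_name<TAB>weight``, heaviest first.

    Equal weights are ordered alphabetically by name so the output is stable.
    Weights are written with full float precision (``repr`` round-trip).
    """
    w = weights.w if isinstance(weights, FeatureWeights) else np.asarray(weights, float)
    names = [str(n) for n in feature_names]
    if len(names) == 0:
        raise ValidationError("empty feature name list")
    if len(names) != w.size:
        raise ValidationError(
            f"{len(names)} names for {w.size} weights"
        )
    order = sorted(range(w.size), key=lambda j: (-w[j], names[j]))
    with open(path, "w") as fh:
        fh.write("feature\tweight\n")
        for j in order:
            fh.write(f"{names[j]}\t{float(w[j])!r}\n")


def read_weights(path) -> tuple[np.ndarray, list]:
    """Read a weights TSV back; returns (weights, names) in file order."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(frame.columns) != ["feature", "weight"]:
        raise SchemaError(f"unexpected weight-file header: {list(frame.columns)}")
    return frame["weight"].to_numpy(dtype=float), frame["feature"].tolist()
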