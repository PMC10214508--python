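"""Subject x feature metabolomics tables: reading, validation, writing, merging.

A feature table holds one row per subject and one column per chemical feature
(feature IDs are often m/z values printed to four decimals, but any unique
string is accepted). Abundance cells may be missing; missing cells are kept as
missing (NaN) at the I/O layer and are only ever imputed inside a training
fold by the evaluation engine, so no information leaks between folds and a
read/write round trip is lossless.

Composite tables concatenate feature blocks acquired with different
instrumental methods (e.g. GC-MS, CE-MS, LC-MS in positive and negative
mode). Subjects missing from any block are excluded from the composite, and
feature IDs are prefixed with their block tag so that identical m/z values
measured by two instruments remain distinct columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CohortLabels",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "merge_composite",
]

#: Tokens recognised as "missing" in CSV/TSV cells (besides the empty cell).
MISSING_TOKENS = ("", "NA")

_SEPARATORS = {"csv": ",", "tsv": "\t"}


class FeatureTableError(ValueError):
    """Raised for invalid tables: duplicate IDs, shape mismatches, bad cells."""


@dataclass
class FeatureTable:
    """Subject x feature abundance matrix.

    Parameters
    ----------
    subject_ids
        Unique subject identifiers, one per matrix row.
    feature_ids
        Unique feature identifiers, one per matrix column.
    values
        Float matrix of shape ``(n_subjects, n_features)``; ``NaN`` marks a
        missing abundance.
    block_tags
        Optional per-feature acquisition-method label (e.g. ``"LC-MS+"``).
    """

    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    block_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def validate(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FeatureTableError("duplicate subject IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FeatureTableError("duplicate feature IDs")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.subject_ids),
            len(self.feature_ids),
        ):
            raise FeatureTableError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        if np.isinf(self.values).any():
            raise FeatureTableError("non-finite (infinite) abundance values")
        if self.block_tags is not None and len(self.block_tags) != len(self.feature_ids):
            raise FeatureTableError("block_tags length does not match feature count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.feature_ids)

    def subset_subjects(self, subject_ids: Sequence[str]) -> "FeatureTable":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return replace(self, subject_ids=list(subject_ids), values=self.values[rows])


@dataclass
class CohortLabels:
    """Binary cohort labels; 1 = disease (positive class), 0 = control."""

    subject_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.y = np.asarray(self.y)
        if len(self.subject_ids) != len(self.y):
            raise FeatureTableError("one label per subject required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise FeatureTableError("duplicate subject IDs in labels")
        values = set(np.unique(self.y).tolist())
        if not values <= {0, 1}:
            raise FeatureTableError(f"labels must be binary 0/1, got {sorted(values)}")
        self.y = self.y.astype(np.int64)

    def aligned_to(self, subject_ids: Sequence[str]) -> "CohortLabels":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            order = [index[s] for s in subject_ids]
        except KeyError as exc:  # pragma: no cover - message detail
            raise FeatureTableError(f"subject {exc} has no label") from exc
        return CohortLabels(list(subject_ids), self.y[order])


def read_feature_table(
    path: str | Path,
    format: str = "csv",
    label_column: str | None = None,
) -> tuple[FeatureTable, CohortLabels | None]:
    """Read a subject x feature table; optionally split out a label column.

    The first column of the file is the subject ID; every remaining column
    (except ``label_column``) is a feature. Empty cells and ``NA`` are read as
    missing; any other non-numeric abundance cell is a parse error.
    """
    sep = _separator(format)
    # pandas silently renames duplicate header fields, so check them raw
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    if len(set(header[1:])) != len(header[1:]):
        raise FeatureTableError("duplicate feature IDs in header")
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise FeatureTableError(f"label column {label_column!r} not in header")
        raw = frame.pop(label_column)
        try:
            y = raw.astype(int).to_numpy()
        except ValueError as exc:
            raise FeatureTableError(f"non-integer label cell: {exc}") from exc
        labels = CohortLabels(list(frame.index), y)

    cells = frame.to_numpy(dtype=object)
    values = np.empty(cells.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(cells):
        text = str(cell).strip()
        if text in MISSING_TOKENS:
            values[i, j] = np.nan
            continue
        try:
            values[i, j] = float(text)
        except ValueError as exc:
            raise FeatureTableError(
                f"non-numeric abundance {text!r} at subject {frame.index[i]!r}, "
                f"feature {frame.columns[j]!r}"
            ) from exc
    table = FeatureTable(list(frame.index), list(frame.columns), values)
    return table, labels


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    format: str = "csv",
    labels: CohortLabels | None = None,
    label_column: str = "label",
) -> Path:
    """Write a table (optionally with a label column) so that a subsequent
    :func:`read_feature_table` reproduces it exactly, missing cells included."""
    if table.n_features == 0:
        raise FeatureTableError("refusing to write a table with no features")
    sep = _separator(format)
    frame = table.to_frame()
    if labels is not None:
        aligned = labels.aligned_to(table.subject_ids)
        frame.insert(0, label_column, aligned.y)
    frame.index.name = "subject"
    path = Path(path)
    # repr-based float formatting keeps the round trip bit-exact
    frame.to_csv(path, sep=sep, na_rep="", float_format=None)
    return path


def merge_composite(
    tables: Sequence[FeatureTable],
    block_names: Sequence[str] | None = None,
) -> FeatureTable:
    """Assemble a composite table from per-instrument feature blocks.

    Subjects are matched across blocks by exact ID equality; any subject
    absent from one or more blocks is excluded. Features are concatenated
    with their IDs prefixed ``"<block>:"`` so blocks that share raw m/z
    values stay distinct. A single-table input is returned unchanged.
    """
    if not tables:
        raise FeatureTableError("merge_composite requires at least one table")
    if len(tables) == 1 and block_names is None:
        return tables[0]

    if block_names is None:
        block_names = []
        for i, t in enumerate(tables):
            tags = set(t.block_tags) if t.block_tags else set()
            block_names.append(tags.pop() if len(tags) == 1 else f"B{i + 1}")
    if len(block_names) != len(tables):
        raise FeatureTableError("one block name per table required")

    common = set(tables[0].subject_ids)
    for t in tables[1:]:
        common &= set(t.subject_ids)
    if not common:
        raise FeatureTableError("no subject is present in every block")
    # deterministic subject order: order of appearance in the first block
    subjects = [s for s in tables[0].subject_ids if s in common]

    feature_ids: list[str] = []
    tags: list[str] = []
    blocks = []
    for name, t in zip(block_names, tables):
        feature_ids.extend(f"{name}:{fid}" for fid in t.feature_ids)
        tags.extend([name] * t.n_features)
        blocks.append(t.subset_subjects(subjects).values)
    if len(set(feature_ids)) != len(feature_ids):
        raise FeatureTableError("prefixed feature IDs collide across blocks")
    return FeatureTable(subjects, feature_ids, np.hstack(blocks), block_tags=tags)


def _separator(format: str) -> str:
    try:
        return _SEPARATORS[format]
    except KeyError:
        raise FeatureTableError(f"unknown format {format!r}; use 'csv' or 'tsv'") from None
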