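"""Core tabular containers for clinical prediction under missing data.

A dataset is a :class:`ClinicalTable`: a real-valued feature matrix with a
per-cell missingness mask, a label vector, and a :class:`FeatureSchema`
declaring which columns are boolean symptoms (coded 0/1) and which are
continuous measurements such as age or course of treatment.  CSV I/O,
missingness-based row exclusion, and the stratified 70/30 split used by
the training protocol live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

BOOLEAN = "boolean"
CONTINUOUS = "continuous"

DEFAULT_MISSING_MARKERS = frozenset({"", "na", "nan"})


class SchemaError(ValueError):
    """The file or table does not match the declared schema."""


class ValidationError(ValueError):
    """A cell value violates a schema invariant."""


@dataclass(frozen=True)
class FeatureSchema:
    """Column names, types, valid ranges and class labels for one dataset."""

    feature_names: Tuple[str, ...]
    feature_types: Tuple[str, ...]
    class_labels: Tuple[str, ...]
    continuous_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    label_column: str = "label"

    def __post_init__(self):
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "feature_types", tuple(self.feature_types))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        if len(self.feature_types) != len(self.feature_names):
            raise SchemaError("feature_types must have one entry per feature name")
        bad = [t for t in self.feature_types if t not in (BOOLEAN, CONTINUOUS)]
        if bad:
            raise SchemaError(f"unknown feature types: {bad}")
        if len(self.class_labels) < 2:
            raise SchemaError("at least two class labels are required")
        if self.label_column in self.feature_names:
            raise SchemaError("label column name collides with a feature name")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def boolean_columns(self) -> np.ndarray:
        return np.array([t == BOOLEAN for t in self.feature_types])

    def continuous_columns(self) -> np.ndarray:
        return ~self.boolean_columns()

    def class_index(self) -> Dict[str, int]:
        return {c: i for i, c in enumerate(self.class_labels)}


@dataclass
class ClinicalTable:
    """Feature matrix + missingness mask + labels, validated against a schema.

    ``values`` is float64 with boolean features coded 0/1 where observed;
    entries under a true ``missing_mask`` cell carry no meaning (NaN by
    convention).  ``labels`` holds class identifiers from the schema.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    labels: np.ndarray
    schema: FeatureSchema

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] != self.schema.n_features:
            raise SchemaError(
                f"values must be n_rows x {self.schema.n_features}, got {self.values.shape}")
        if self.missing_mask.shape != self.values.shape:
            raise SchemaError("missing_mask shape must match values")
        if self.labels.shape != (self.values.shape[0],):
            raise SchemaError("labels must have one entry per row")
        known = set(self.schema.class_labels)
        unknown = sorted({l for l in self.labels} - known)
        if unknown:
            raise ValidationError(f"labels not in schema.class_labels: {unknown}")
        bool_cols = self.schema.boolean_columns()
        observed = ~self.missing_mask[:, bool_cols]
        vals = self.values[:, bool_cols]
        bad = observed & ~np.isin(vals, (0.0, 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            col = np.array(self.schema.feature_names)[bool_cols][c]
            raise ValidationError(
                f"non-binary value {vals[r, c]!r} in boolean column {col!r} (row {r})")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_indices(self) -> np.ndarray:
        """Labels as integer indices into ``schema.class_labels``."""
        lookup = self.schema.class_index()
        return np.array([lookup[l] for l in self.labels], dtype=np.int64)

    def missing_per_row(self) -> np.ndarray:
        return self.missing_mask.sum(axis=1)

    def take_rows(self, indices: Union[np.ndarray, Sequence[int]]) -> "ClinicalTable":
        idx = np.asarray(indices, dtype=np.int64)
        return ClinicalTable(self.values[idx].copy(), self.missing_mask[idx].copy(),
                             self.labels[idx].copy(), self.schema)

    def copy(self) -> "ClinicalTable":
        return ClinicalTable(self.values.copy(), self.missing_mask.copy(),
                             self.labels.copy(), self.schema)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/test row-index sets over the retained rows."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self):
        tr = np.asarray(self.train_indices, dtype=np.int64)
        te = np.asarray(self.test_indices, dtype=np.int64)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        if np.intersect1d(tr, te).size:
            raise ValidationError("train and test indices overlap")


def read_table(path: Union[str, Path], schema: FeatureSchema,
               missing_markers: Set[str] = DEFAULT_MISSING_MARKERS) -> ClinicalTable:
    """Read a CSV with a header row into a validated :class:`ClinicalTable`.

    Cells equal to any missing marker (case-insensitive; empty string, "NA"
    and "NaN" by default) become masked.  Boolean columns must contain only
    0/1; offenders are reported with 1-based CSV row numbers (header = row 1).
    """
    markers = {m.lower() for m in missing_markers}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(schema.feature_names) | {schema.label_column}
    got = set(df.columns)
    if got != expected:
        extra, miss = sorted(got - expected), sorted(expected - got)
        raise SchemaError(f"header mismatch: unexpected columns {extra}, "
                          f"missing columns {miss}")
    n = len(df)
    values = np.full((n, schema.n_features), np.nan)
    mask = np.zeros((n, schema.n_features), dtype=bool)
    for j, (name, ftype) in enumerate(zip(schema.feature_names, schema.feature_types)):
        col = df[name].astype(str)
        for i, raw in enumerate(col):
            cell = raw.strip()
            if cell.lower() in markers:
                mask[i, j] = True
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValidationError(
                    f"cannot parse {cell!r} in column {name!r}, CSV row {i + 2}")
            if ftype == BOOLEAN and v not in (0.0, 1.0):
                raise ValidationError(
                    f"non-binary value {cell!r} in boolean column {name!r}, CSV row {i + 2}")
            values[i, j] = v
    labels = []
    known = set(schema.class_labels)
    for i, raw in enumerate(df[schema.label_column].astype(str)):
        cell = raw.strip()
        if cell not in known:
            raise ValidationError(
                f"unknown label {cell!r} in CSV row {i + 2}")
        labels.append(cell)
    return ClinicalTable(values, mask, np.array(labels, dtype=object), schema)


def write_table(table: ClinicalTable, path: Union[str, Path]) -> None:
    """Write a table to CSV; missing cells are emitted as empty strings."""
    bool_cols = table.schema.boolean_columns()
    cols: Dict[str, List[str]] = {}
    for j, name in enumerate(table.schema.feature_names):
        out: List[str] = []
        for i in range(table.n_rows):
            if table.missing_mask[i, j]:
                out.append("")
            elif bool_cols[j]:
                out.append(str(int(table.values[i, j])))
            else:
                out.append(repr(float(table.values[i, j])))
        cols[name] = out
    cols[table.schema.label_column] = [str(l) for l in table.labels]
    pd.DataFrame(cols).to_csv(path, index=False)


def filter_rows_by_missingness(table: ClinicalTable, max_missing: int) -> ClinicalTable:
    """Drop rows with more than ``max_missing`` missing cells; order preserved.

    The study protocol excludes records with more than three missing values,
    i.e. ``max_missing=3``.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be non-negative")
    keep = np.flatnonzero(table.missing_per_row() <= max_missing)
    return table.take_rows(keep)


def stratified_split(table: ClinicalTable, train_fraction: float,
                     seed: int) -> DataSplit:
    """Stratified split with ``floor(train_fraction * n)`` training rows.

    Per-class training quotas are apportioned by largest remainder so the
    total is exact (this reproduces 1,344/576 on n=1,920, 478/205 on n=683
    and 537/231 on n=768 at fraction 0.7); membership within each class is
    randomized by ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = table.n_rows
    target = math.floor(train_fraction * n)
    class_rows = []
    for c in table.schema.class_labels:
        rows = np.flatnonzero(table.labels == c)
        if rows.size == 0:
            raise ValidationError(f"class {c!r} has no rows; cannot stratify")
        class_rows.append(rows)
    quotas = [train_fraction * rows.size for rows in class_rows]
    base = [math.floor(q) for q in quotas]
    deficit = target - sum(base)
    # largest fractional remainder first; ties to the larger class, then index
    order = sorted(range(len(quotas)),
                   key=lambda k: (-(quotas[k] - base[k]), -class_rows[k].size, k))
    for k in order[:deficit]:
        base[k] += 1
    rng = np.random.default_rng(seed)
    train, test = [], []
    for rows, k in zip(class_rows, base):
        perm = rng.permutation(rows)
        train.append(perm[:k])
        test.append(perm[k:])
    return DataSplit(np.sort(np.concatenate(train)), np.sort(np.concatenate(test)))
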