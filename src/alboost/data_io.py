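"""Compound feature tables: loading, validation and z-score normalization.

The central container is :class:`FeatureTable`: one row per compound, one
column per numeric molecular descriptor (logP, PSA, topological indices,
ligand efficiencies, ...), plus a binary class label such as drug/non-drug
or one disease category versus another. Tables are exchanged as plain CSV
with a ``compound_id`` column, a label column and numeric feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "NormStats",
    "read_feature_table",
    "write_feature_table",
    "fit_normalizer",
    "apply_normalizer",
]

ID_COLUMN = "compound_id"


@dataclass
class FeatureTable:
    """A validated two-class compound table.

    Parameters
    ----------
    compound_ids
        Unique compound identifiers, one per row.
    feature_names
        Names of the ``d`` descriptor columns.
    matrix
        ``n x d`` float array of descriptor values, in whatever units the
        descriptors were provided.
    labels
        Per-compound class tag; must take exactly the two values declared
        in ``class_names``.
    class_names
        Ordered pair ``(positive, negative)``; the positive class is the
        "active" one (e.g. drug).
    """

    compound_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, d = self.matrix.shape
        if n < 1 or d < 1:
            raise ValueError("feature table must have at least one row and one feature")
        if len(self.compound_ids) != n:
            raise ValueError("compound_ids length does not match matrix rows")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match matrix columns")
        if len(set(self.compound_ids)) != n:
            dupes = sorted({c for c in self.compound_ids if self.compound_ids.count(c) > 1})
            raise ValueError(f"duplicate compound ids: {dupes}")
        if len(self.labels) != n:
            raise ValueError("labels length does not match matrix rows")
        if len(self.class_names) != 2 or self.class_names[0] == self.class_names[1]:
            raise ValueError("class_names must be two distinct values")
        bad = sorted(set(self.labels) - set(self.class_names))
        if bad:
            raise ValueError(f"labels outside declared classes {self.class_names}: {bad}")
        if not np.all(np.isfinite(self.matrix)):
            i, j = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValueError(
                f"non-finite feature value at row {self.compound_ids[i]!r}, "
                f"column {self.feature_names[j]!r}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Integer labels: 0 for the positive (active) class, 1 for the negative."""
        return np.where(self.labels == self.class_names[0], 0, 1)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_names}

    def select(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset in the given order (labels and ids carried along)."""
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            compound_ids=[self.compound_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            class_names=self.class_names,
        )

    def with_matrix(self, matrix: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            compound_ids=list(self.compound_ids),
            feature_names=list(self.feature_names),
            matrix=matrix,
            labels=self.labels.copy(),
            class_names=self.class_names,
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        frame = pd.DataFrame(self.matrix, columns=self.feature_names)
        frame.insert(0, ID_COLUMN, self.compound_ids)
        frame.insert(1, label_column, self.labels)
        return frame


@dataclass
class NormStats:
    """Per-feature mean and population standard deviation."""

    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean and scale must have the same length")
        if np.any(self.scale < 0):
            raise ValueError("scale must be non-negative")


def read_feature_table(
    path: str | Path,
    label_column: str,
    positive_class: str,
    negative_class: str | None = None,
) -> FeatureTable:
    """Load a compound table from CSV.

    The file must have a header naming ``compound_id``, `label_column` and at
    least one feature column. Every feature cell must parse as a number;
    a non-numeric cell raises with the offending row and column named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (ID_COLUMN, label_column):
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    feature_names = [c for c in raw.columns if c not in (ID_COLUMN, label_column)]
    if not feature_names:
        raise ValueError(f"no feature columns in {path}")

    ids = raw[ID_COLUMN].tolist()
    labels = raw[label_column].to_numpy(dtype=object)
    observed = set(labels)
    if negative_class is None:
        others = sorted(observed - {positive_class})
        if len(others) != 1:
            raise ValueError(
                f"cannot infer negative class: labels present are {sorted(observed)}"
            )
        negative_class = others[0]

    matrix = np.empty((len(raw), len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        col = pd.to_numeric(raw[name], errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-numeric value {raw[name].iloc[i]!r} in column {name!r} "
                f"at row {ids[i]!r}"
            )
        matrix[:, j] = col.to_numpy(dtype=float)

    return FeatureTable(
        compound_ids=ids,
        feature_names=feature_names,
        matrix=matrix,
        labels=labels,
        class_names=(positive_class, negative_class),
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, label_column: str = "label"
) -> None:
    table.to_frame(label_column).to_csv(path, index=False)


def fit_normalizer(table: FeatureTable) -> NormStats:
    """Per-feature mean and population standard deviation (divisor n)."""
    if table.n < 2:
        raise ValueError("need at least two compounds to fit normalization statistics")
    return NormStats(
        mean=table.matrix.mean(axis=0),
        scale=table.matrix.std(axis=0),  # ddof=0: population sd
        feature_names=list(table.feature_names),
    )


def apply_normalizer(table: FeatureTable, stats: NormStats) -> FeatureTable:
    """z-score each feature; zero-variance features map to exactly 0."""
    if stats.mean.shape[0] != table.d:
        raise ValueError(
            f"normalizer has {stats.mean.shape[0]} features, table has {table.d}"
        )
    scale = np.where(stats.scale == 0, 1.0, stats.scale)
    z = (table.matrix - stats.mean) / scale
    z[:, stats.scale == 0] = 0.0
    return table.with_matrix(z)
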