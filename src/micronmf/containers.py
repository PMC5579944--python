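"""Core data containers for count matrices and factorization results.

The universal input is a ``CountMatrix``: a p x n table of non-negative
integer counts whose rows are OTUs (or enzyme/gene reaction groups) and
whose columns are samples.  A fitted factorization X ~ T W is carried by a
``TypeMatrix`` T (p x k, columns are subcommunity compositions summing to 1)
and a ``WeightMatrix`` W (k x n, raw columns sum to each sample's
sequencing depth; normalized columns sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TypeMatrix",
    "WeightMatrix",
    "ClassPartition",
]

_COL_SUM_TOL = 1e-8


def _as_labels(labels, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} {prefix!r} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {prefix!r} labels")
    return labels


@dataclass
class CountMatrix:
    """p x n non-negative integer count table with row/column labels.

    Parameters
    ----------
    values : array-like of shape (p, n)
        Counts; must be non-negative and integral.  All-zero sample
        columns are rejected (a sample with zero sequencing depth carries
        no information and breaks the per-sample regressions).  All-zero
        feature rows are retained: they simply contribute nothing to any
        type.
    feature_ids, sample_ids : sequences of str, optional
        Row and column labels; autogenerated when omitted.
    """

    values: np.ndarray
    feature_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("count matrix must be two-dimensional")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(f"negative count at row {i}, column {j}")
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(f"non-integer count at row {i}, column {j}")
        col_sums = values.sum(axis=0)
        if np.any(col_sums == 0):
            j = int(np.argmin(col_sums))
            raise ValueError(f"sample column {j} is all zero")
        self.values = values
        self.feature_ids = _as_labels(self.feature_ids, values.shape[0], "OTU")
        self.sample_ids = _as_labels(self.sample_ids, values.shape[1], "S")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (column sums)."""
        return self.values.sum(axis=0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.feature_ids, columns=self.sample_ids
        )

    def select_samples(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.values[:, idx],
            self.feature_ids,
            [self.sample_ids[i] for i in idx],
        )


@dataclass
class TypeMatrix:
    """p x k matrix of subcommunity compositions; each column sums to 1."""

    values: np.ndarray
    feature_ids: list[str] = field(default=None)
    type_ids: list[str] = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("type matrix must be two-dimensional")
        if np.any(values < 0):
            raise ValueError("type matrix has negative entries")
        col_sums = values.sum(axis=0)
        if np.any(np.abs(col_sums - 1.0) > _COL_SUM_TOL):
            raise ValueError(
                "type matrix columns must sum to 1 "
                f"(column sums: {np.array2string(col_sums, precision=6)})"
            )
        self.values = values
        self.feature_ids = _as_labels(self.feature_ids, values.shape[0], "OTU")
        self.type_ids = _as_labels(self.type_ids, values.shape[1], "type")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.type_ids)


@dataclass
class WeightMatrix:
    """k x n matrix of per-sample mixing weights over types.

    Raw-scale columns sum to the sample's sequencing depth; normalized
    columns sum to 1 (the form used as classifier input and for plotting).
    """

    values: np.ndarray
    normalized: bool = False
    type_ids: list[str] = field(default=None)
    sample_ids: list[str] = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("weight matrix must be two-dimensional")
        if np.any(values < 0):
            raise ValueError("weight matrix has negative entries")
        if self.normalized:
            col_sums = values.sum(axis=0)
            if np.any(np.abs(col_sums - 1.0) > _COL_SUM_TOL):
                raise ValueError("normalized weight columns must sum to 1")
        self.values = values
        self.type_ids = _as_labels(self.type_ids, values.shape[0], "type")
        self.sample_ids = _as_labels(self.sample_ids, values.shape[1], "S")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def normalize(self) -> "WeightMatrix":
        """Return the unit-column-sum form (depth divided out)."""
        sums = self.values.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize a weight column summing to 0")
        return WeightMatrix(
            self.values / sums, normalized=True,
            type_ids=self.type_ids, sample_ids=self.sample_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.type_ids, columns=self.sample_ids)


@dataclass
class ClassPartition:
    """Per-sample class labels over g non-empty classes."""

    labels: np.ndarray
    class_ids: list[str] = field(default=None)

    def __post_init__(self):
        labels = np.asarray([str(x) for x in np.asarray(self.labels).ravel()])
        if labels.size == 0:
            raise ValueError("empty label vector")
        present = sorted(set(labels))
        if self.class_ids is None:
            self.class_ids = present
        else:
            self.class_ids = [str(c) for c in self.class_ids]
            missing = set(self.class_ids) - set(present)
            if missing:
                raise ValueError(f"empty class(es): {sorted(missing)}")
            extra = set(present) - set(self.class_ids)
            if extra:
                raise ValueError(f"labels outside declared classes: {sorted(extra)}")
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def g(self) -> int:
        return len(self.class_ids)

    def indices_of(self, class_id: str) -> np.ndarray:
        return np.flatnonzero(self.labels == str(class_id))

    def select(self, idx) -> "ClassPartition":
        sub = self.labels[np.asarray(idx)]
        return ClassPartition(sub, class_ids=sorted(set(sub)))
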