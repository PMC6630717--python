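"""Shared in-memory containers for domain-count, similarity and distance data.

All three containers wrap a labelled :class:`pandas.DataFrame`. The wrappers
exist to carry the semantic tag (count transform, distance model) that the
file formats persist, and to validate the structural invariants each kind of
matrix must satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised count-matrix transforms.
TRANSFORMS = ("raw", "binary", "log1p", "frequency")

#: Recognised distance models.
DISTANCE_MODELS = ("p", "jukes_cantor", "poisson_aa", "correlation", "euclidean", "patristic")


class MatrixError(ValueError):
    """Raised when a matrix violates a structural invariant."""


@dataclass
class DomainCountMatrix:
    """Domain x sample matrix of non-negative values plus a transform tag.

    Rows are domain identifiers, columns are sample (or species) identifiers.
    ``transform`` records which representation the values are in:

    raw
        non-negative integer occurrence counts
    binary
        0/1 presence-absence
    log1p
        natural log of (count + 1)
    frequency
        per-sample relative frequencies (columns sum to 1, or 0 for an
        empty sample)
    """

    data: pd.DataFrame
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise MatrixError(f"unknown transform {self.transform!r}")
        if self.data.index.has_duplicates:
            raise MatrixError("duplicate domain (row) ids")
        if self.data.columns.has_duplicates:
            raise MatrixError("duplicate sample (column) ids")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise MatrixError("negative values in count matrix")
        if self.transform == "raw" and values.size:
            if not np.allclose(values, np.round(values)):
                raise MatrixError("raw counts must be integers")
        if self.transform == "binary" and values.size:
            if not np.isin(values, (0.0, 1.0)).all():
                raise MatrixError("binary matrix must contain only 0/1")
        if self.transform == "frequency" and values.size:
            sums = values.sum(axis=0)
            ok = np.isclose(sums, 1.0) | np.isclose(sums, 0.0)
            if not ok.all():
                raise MatrixError("frequency columns must sum to 1 (or 0 when empty)")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:  # labels, values and tag
        if not isinstance(other, DomainCountMatrix):
            return NotImplemented
        return (
            self.transform == other.transform
            and self.row_ids == other.row_ids
            and self.col_ids == other.col_ids
            and np.allclose(self.values(), other.values(), atol=0, rtol=0)
        )


def _check_square_symmetric(data: pd.DataFrame, what: str) -> None:
    if data.shape[0] != data.shape[1]:
        raise MatrixError(f"{what} must be square")
    if list(data.index) != list(data.columns):
        raise MatrixError(f"{what} row and column ids must match")
    values = data.to_numpy(dtype=float)
    finite = np.isfinite(values)
    both = finite & finite.T
    if not np.allclose(values[both], values.T[both], atol=1e-12):
        raise MatrixError(f"{what} must be symmetric")


@dataclass
class SimilarityMatrix:
    """Symmetric all-pairs Pearson correlation of domain profiles.

    Diagonal is exactly 1; off-diagonal entries lie in [-1, 1] or are NaN for
    pairs involving a zero-variance profile.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_square_symmetric(self.data, "similarity matrix")
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if not np.allclose(np.diag(values), 1.0):
                raise MatrixError("similarity diagonal must be exactly 1")
            off = values[~np.eye(len(values), dtype=bool)]
            off = off[np.isfinite(off)]
            if off.size and (np.abs(off) > 1 + 1e-12).any():
                raise MatrixError("correlations must lie in [-1, 1]")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        """Unique unordered pairs as a long table (id1, id2, r)."""
        ids = self.ids
        rows = []
        vals = self.values()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], vals[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "r"])


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distance matrix with a model tag."""

    data: pd.DataFrame
    model: str = "p"

    def __post_init__(self) -> None:
        if self.model not in DISTANCE_MODELS:
            raise MatrixError(f"unknown distance model {self.model!r}")
        _check_square_symmetric(self.data, "distance matrix")
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if not np.allclose(np.diag(values), 0.0):
                raise MatrixError("distance diagonal must be zero")
            finite = values[np.isfinite(values)]
            if finite.size and finite.min() < -1e-12:
                raise MatrixError("distances must be non-negative")
            if self.model == "p" and finite.size and finite.max() > 1 + 1e-12:
                raise MatrixError("p-distances must lie in [0, 1]")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_long(self) -> pd.DataFrame:
        ids = self.ids
        vals = self.values()
        rows = [
            (ids[i], ids[j], vals[i, j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        return pd.DataFrame(rows, columns=["id1", "id2", "d"])


@dataclass
class Dendrogram:
    """Result of agglomerative clustering as a merge sequence.

    Nodes ``0..n-1`` are the leaves (in ``leaf_ids`` order); the *i*-th merge
    creates node ``n + i``. ``merges`` holds ``(left, right, height)`` with
    heights non-decreasing. ``support`` optionally maps an internal node id to
    its bootstrap proportion in percent.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]
    support: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(set(self.leaf_ids)) != n:
            raise MatrixError("leaf labels must be unique")
        if len(self.merges) != max(n - 1, 0):
            raise MatrixError(f"expected {n - 1} merges for {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_leafsets(self) -> dict[int, frozenset[str]]:
        """Leaf-label set under every node (leaves and internal)."""
        n = self.n_leaves
        sets: dict[int, frozenset[str]] = {
            i: frozenset([label]) for i, label in enumerate(self.leaf_ids)
        }
        for i, (a, b, _h) in enumerate(self.merges):
            sets[n + i] = sets[a] | sets[b]
        return sets

    def clusters(self) -> set[frozenset[str]]:
        """Leaf sets of the internal nodes (the clades the tree asserts)."""
        n = self.n_leaves
        sets = self.node_leafsets()
        return {sets[n + i] for i in range(len(self.merges))}

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the dendrogram drawing."""
        if not self.merges:
            return list(self.leaf_ids)
        n = self.n_leaves

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b, _ = self.merges[node - n]
            return walk(a) + walk(b)

        root = n + len(self.merges) - 1
        return [self.leaf_ids[i] for i in walk(root)]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into exactly ``k`` flat clusters (labels 0..k-1).

        Applies the first ``n - k`` merges and labels the resulting groups in
        order of their smallest leaf index.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        parent = list(range(n + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, (a, b, _h) in enumerate(self.merges[: n - k]):
            node = n + i
            parent[find(a)] = node
            parent[find(b)] = node
        roots: dict[int, int] = {}
        labels: dict[str, int] = {}
        for i, leaf in enumerate(self.leaf_ids):
            r = find(i)
            if r not in roots:
                roots[r] = len(roots)
            labels[leaf] = roots[r]
        return labels


@dataclass
class PCAResult:
    """Principal component analysis of a sample x domain data matrix."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # domains x components
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pair_index(ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of ids, in row-major upper-triangle order."""
    ids = list(ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
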