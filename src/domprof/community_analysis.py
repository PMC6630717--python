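"""Clustering and ordination of samples by domain frequency profile.

The environmental workflow: samples are compared by Pearson correlation of
their domain frequency profiles, turned into a correlation distance
``d = 1 - r``, clustered agglomeratively with the Ward.D2 criterion, and
given bootstrap support by resampling domain rows. Flat clusters from the
dendrogram are scored against sample covariates (filter pore size, season,
depth, station) with the adjusted Rand index; PCA plus silhouette scores
rank which covariate best explains the sample separation.

Ward.D2 here is the convention of R's ``hclust(method="ward.D2")``: the
input dissimilarities are used as-is (not squared beforehand) and the merge
criterion minimises the increase in within-cluster variance, giving the
Lance-Williams update

    d(k, i+j) = sqrt[ ((n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2)
                      / (n_i+n_j+n_k) ].

Ties are broken by merging the pair with the lexicographically smallest
node indices (leaves first, then merge-creation order), so the merge
sequence is deterministic for a given input order.

Bootstrap support is the plain bootstrap proportion (BP): the percentage of
row-resampled replicates whose dendrogram contains the same leaf set under
a node. Multiscale-bootstrap AU p-values are a possible extension.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .containers import (
    Dendrogram,
    DistanceMatrix,
    DomainCountMatrix,
    PCAResult,
    SimilarityMatrix,
)
from .domain_matrix import pairwise_profile_correlation, transform_log1p

logger = logging.getLogger(__name__)


def correlation_distance(similarity: SimilarityMatrix) -> DistanceMatrix:
    """Turn profile correlations into the dissimilarity d = 1 - r (range [0, 2])."""
    values = 1.0 - similarity.values()
    np.fill_diagonal(values, 0.0)
    if np.isnan(values).any():
        logger.warning("NaN correlations propagate to NaN distances")
    return DistanceMatrix(
        pd.DataFrame(values, index=similarity.ids, columns=similarity.ids),
        model="correlation",
    )


def hclust_ward2(distance: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with the Ward.D2 criterion.

    Merge heights are the between-cluster Ward distances; they are
    non-decreasing (the criterion is reducible, so no inversions occur).
    """
    ids = distance.ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    values = distance.values()
    if not np.isfinite(values).all():
        bad = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not np.isfinite(values[i, j])
        ]
        raise ValueError(f"non-finite distances for pairs: {bad}")

    # active clusters: node id -> (size,); squared inter-cluster distances
    d2: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = values[i, j] ** 2
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    next_node = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                pair = key(active[ai], active[bi])
                cand = (d2[pair], pair)
                if best is None or cand < best:
                    best = cand
        (best_d2, (a, b)) = best
        height = float(np.sqrt(max(best_d2, 0.0)))
        merges.append((a, b, height))
        new = next_node
        next_node += 1
        na, nb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            nc = size[c]
            dac, dbc = d2[key(a, c)], d2[key(b, c)]
            d2[key(new, c)] = ((na + nc) * dac + (nb + nc) * dbc - nc * best_d2) / (
                na + nb + nc
            )
        size[new] = na + nb
        active = [c for c in active if c not in (a, b)] + [new]
    return Dendrogram(leaf_ids=list(ids), merges=merges)


def bootstrap_support(
    matrix: DomainCountMatrix, B: int = 1000, seed: int = 0
) -> Dendrogram:
    """Dendrogram of the samples with bootstrap proportions on internal nodes.

    The reference dendrogram comes from Ward.D2 on the correlation distance
    of the full matrix; each of the B replicates resamples domain rows with
    replacement and recomputes the whole pipeline. BP of a node is the
    percentage of replicates whose dendrogram contains the same leaf set.
    Replicate correlations that are undefined (a resampled profile with zero
    variance) are treated as r = 0 for that replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for bootstrap support")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 domain rows to resample")

    ids = matrix.col_ids

    def cluster(X: np.ndarray) -> Dendrogram:
        centered = X - X.mean(axis=0, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=0))
        unit = centered / np.where(norms == 0, 1.0, norms)
        r = np.clip(unit.T @ unit, -1.0, 1.0)
        r[norms == 0, :] = 0.0  # zero-variance resample: treat as uncorrelated
        r[:, norms == 0] = 0.0
        np.fill_diagonal(r, 1.0)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        return hclust_ward2(
            DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), model="correlation")
        )

    values = matrix.values()
    reference = cluster(values)
    target_sets = reference.node_leafsets()
    n = reference.n_leaves
    counts = {n + i: 0 for i in range(len(reference.merges))}

    rng = np.random.default_rng(seed)
    nrows = matrix.shape[0]
    for _ in range(B):
        rep_clusters = cluster(values[rng.integers(0, nrows, size=nrows)]).clusters()
        for node in counts:
            if target_sets[node] in rep_clusters:
                counts[node] += 1
    support = {node: 100.0 * c / B for node, c in counts.items()}
    return Dendrogram(
        leaf_ids=reference.leaf_ids, merges=reference.merges, support=support
    )


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut the merge sequence into exactly k flat clusters."""
    return dendrogram.cut(k)


def cluster_metadata_agreement(
    labels: Mapping[str, int], metadata_values: Mapping[str, object]
) -> float:
    """Adjusted Rand index between cluster labels and a metadata grouping."""
    if set(labels) != set(metadata_values):
        raise ValueError("cluster labels and metadata must cover the same samples")
    samples = sorted(labels)
    a = [labels[s] for s in samples]
    b = [str(metadata_values[s]) for s in samples]
    return float(adjusted_rand_score(a, b))


def heatmap_layout(
    matrix: DomainCountMatrix,
    row_cluster: bool = True,
    col_cluster: bool = True,
) -> tuple[list[str], list[str], Dendrogram | None, Dendrogram | None]:
    """Row/column orders for a clustered heatmap.

    Columns (samples) are ordered by the Ward.D2 dendrogram on correlation
    distance; rows (domains) by Ward.D2 on Euclidean distance of their
    log1p-transformed count vectors. Returns (row_order, col_order,
    row_dendrogram, col_dendrogram); disabled axes keep input order with a
    None dendrogram.
    """
    if matrix.data.empty:
        raise ValueError("empty matrix")
    row_order = matrix.row_ids
    col_order = matrix.col_ids
    row_dend = col_dend = None
    if col_cluster and matrix.shape[1] >= 2:
        sim = pairwise_profile_correlation(matrix)
        col_dend = hclust_ward2(correlation_distance(sim))
        col_order = col_dend.leaf_order()
    if row_cluster and matrix.shape[0] >= 2:
        logged = (
            transform_log1p(matrix).values() if matrix.transform == "raw" else matrix.values()
        )
        diffs = logged[:, None, :] - logged[None, :, :]
        dvals = np.sqrt((diffs**2).sum(axis=2))
        row_dist = DistanceMatrix(
            pd.DataFrame(dvals, index=matrix.row_ids, columns=matrix.row_ids),
            model="euclidean",
        )
        row_dend = hclust_ward2(row_dist)
        row_order = row_dend.leaf_order()
    return row_order, col_order, row_dend, col_dend


def heatmap_long_table(matrix: DomainCountMatrix, row_order: Sequence[str], col_order: Sequence[str]) -> pd.DataFrame:
    """Plot-ready long table (domain, sample, value) in heatmap order."""
    df = matrix.data.loc[list(row_order), list(col_order)]
    long = df.stack().rename("value").reset_index()
    long.columns = ["domain_id", "sample_id", "value"]
    return long


def pca(
    matrix: DomainCountMatrix, n_components: int = 3, scale: bool = False
) -> PCAResult:
    """PCA of samples in domain space by singular value decomposition.

    Columns of the count matrix are the samples; the analysis centers (and
    optionally unit-variance scales) each domain across samples. Component
    signs follow the convention that each component's largest-magnitude
    loading is positive. Explained-variance fractions are relative to the
    total variance, so they sum to 1 when all components are kept.
    """
    X = matrix.values().T  # samples x domains
    n_samples, n_domains = X.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    max_comp = min(n_samples - 1, n_domains)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd == 0, 1.0, sd)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s**2).sum()
    comps = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    for c in range(n_components):
        pivot = np.argmax(np.abs(comps[c]))
        if comps[c, pivot] < 0:
            comps[c] *= -1
            scores[:, c] *= -1
    frac = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.col_ids, columns=comp_names),
        loadings=pd.DataFrame(comps.T, index=matrix.row_ids, columns=comp_names),
        explained_variance_fraction=np.asarray(frac),
    )


def group_separation(
    scores: pd.DataFrame,
    groups: Mapping[str, object],
    components: Sequence[str] | None = None,
) -> float:
    """Mean silhouette of a sample grouping in PCA score space.

    Euclidean distance over the chosen components (default: all). Singleton
    groups take silhouette 0 (the standard convention). Requires at least
    two distinct groups.
    """
    if set(scores.index) != set(groups):
        raise ValueError("groups must cover exactly the scored samples")
    cols = list(components) if components is not None else list(scores.columns)
    X = scores.loc[:, cols].to_numpy(dtype=float)
    labels = [str(groups[s]) for s in scores.index]
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 distinct groups")
    if len(set(labels)) == len(labels):
        return 0.0  # all singletons
    return float(silhouette_score(X, labels, metric="euclidean"))


def rank_factors(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: Sequence[str],
    components: Sequence[str] | None = None,
) -> pd.Series:
    """Silhouette score per candidate metadata factor, best first."""
    sil = {
        f: group_separation(scores, metadata.loc[scores.index, f].to_dict(), components)
        for f in factors
    }
    return pd.Series(sil).sort_values(ascending=False)
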