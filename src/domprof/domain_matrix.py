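"""Domain count matrices, their transforms, and all-pairs profile correlation.

The central object of the method: a domains x samples count matrix built by
tallying domain hits per sample. Genomes (or metagenome samples) are then
compared by the Pearson correlation of their domain-count columns, under one
of three representations: raw occurrence counts, 0/1 presence-absence, or
ln(count + 1). Multiple hits of the same domain on one protein count
individually (occurrence counting).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import DomainCountMatrix, SimilarityMatrix
from .formats_io import DomainHit

logger = logging.getLogger(__name__)


def n_pairs(n: int) -> int:
    """Number of unordered pairs among n items, n*(n-1)/2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) // 2


def count_domains(
    hits_by_sample: Mapping[str, Iterable[DomainHit]],
    matched_only: bool = False,
) -> DomainCountMatrix:
    """Tally domain occurrences per sample into a raw count matrix.

    Cell (d, s) is the number of hits with domain id ``d`` in sample ``s``.
    The row set is the union of domains over all samples, sorted; domains
    absent from a sample count 0. ``matched_only`` drops hits whose matched
    flag is false before tallying.
    """
    if not hits_by_sample:
        raise ValueError("at least one sample is required")
    counts: dict[str, dict[str, int]] = {}
    for sample, hits in hits_by_sample.items():
        tally: dict[str, int] = {}
        for h in hits:
            if matched_only and not h.matched:
                continue
            tally[h.domain_id] = tally.get(h.domain_id, 0) + 1
        counts[sample] = tally
    domains = sorted(set().union(*(c.keys() for c in counts.values())) or set())
    data = pd.DataFrame(
        {s: [counts[s].get(d, 0) for d in domains] for s in counts},
        index=pd.Index(domains, name="domain_id"),
        dtype=int,
    )
    return DomainCountMatrix(data, transform="raw")


def _require_raw(matrix: DomainCountMatrix, op: str) -> None:
    if matrix.transform != "raw":
        raise ValueError(f"{op} requires a raw count matrix, got {matrix.transform!r}")


def transform_binary(matrix: DomainCountMatrix) -> DomainCountMatrix:
    """Presence/absence: 1 where the count is >= 1, else 0."""
    _require_raw(matrix, "transform_binary")
    data = (matrix.data >= 1).astype(int)
    return DomainCountMatrix(data, transform="binary")


def transform_log1p(matrix: DomainCountMatrix) -> DomainCountMatrix:
    """Natural log of (count + 1)."""
    _require_raw(matrix, "transform_log1p")
    values = matrix.data.to_numpy(dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("negative counts")
    data = pd.DataFrame(np.log1p(values), index=matrix.data.index, columns=matrix.data.columns)
    return DomainCountMatrix(data, transform="log1p")


def to_frequencies(matrix: DomainCountMatrix) -> DomainCountMatrix:
    """Per-sample relative frequencies (each column divided by its sum)."""
    _require_raw(matrix, "to_frequencies")
    values = matrix.data.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning(
            "samples with zero total counts left as zero columns: %s",
            [c for c, z in zip(matrix.col_ids, zero) if z],
        )
    safe = np.where(zero, 1.0, sums)
    data = pd.DataFrame(values / safe, index=matrix.data.index, columns=matrix.data.columns)
    return DomainCountMatrix(data, transform="frequency")


def apply_transform(matrix: DomainCountMatrix, transform: str) -> DomainCountMatrix:
    """Dispatch to the named transform (``raw`` returns the input)."""
    if transform == "raw":
        return matrix
    if transform == "binary":
        return transform_binary(matrix)
    if transform == "log1p":
        return transform_log1p(matrix)
    if transform in ("frequency", "freq"):
        return to_frequencies(matrix)
    raise ValueError(f"unknown transform {transform!r}")


def pairwise_profile_correlation(matrix: DomainCountMatrix) -> SimilarityMatrix:
    """Pearson r between every pair of sample columns.

    The correlation is computed over the full shared domain-row vector,
    including rows where both samples are zero. Pairs involving a
    zero-variance (constant) column are set to NaN and reported via a
    warning, never silently dropped.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.values()  # domains x samples
    centered = X - X.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=0))
    constant = norms == 0
    if constant.any():
        logger.warning(
            "constant-profile samples produce NaN correlations: %s",
            [c for c, z in zip(matrix.col_ids, constant) if z],
        )
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe
    r = unit.T @ unit
    r = np.clip(r, -1.0, 1.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    data = pd.DataFrame(r, index=matrix.col_ids, columns=matrix.col_ids)
    return SimilarityMatrix(data)


def profile_correlation_pairs(matrix: DomainCountMatrix) -> pd.DataFrame:
    """Long-format unique pairs (id1, id2, r) of the profile correlations."""
    return pairwise_profile_correlation(matrix).to_long()
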