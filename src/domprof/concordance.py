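"""Concordance between domain-profile similarity and marker-gene distance.

For every pair of species present in both a profile-correlation matrix and a
marker distance matrix, the pair's (r_domain, d_marker) point joins a dot
cloud; the Pearson correlation of that cloud measures how well domain
composition tracks marker-gene divergence.

Caveat on inference: the n(n-1)/2 pairwise points are not independent (each
species enters n-1 pairs), so the naive t-test p-value is optimistic. It is
reported because it is the field's conventional summary; a Mantel
permutation test over species labels is provided as the defensible
alternative.

The cloud's Pearson r is reported signed. With similarity on one axis and
distance on the other, a concordant signal is *negative*; published analyses
sometimes print the magnitude. Reports therefore carry both ``r`` and
``abs_r``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DistanceMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


def match_pairs(
    similarity: SimilarityMatrix,
    distance: DistanceMatrix,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Pair up the two matrices over their common species.

    Returns one row per unordered pair of common species with columns
    (id1, id2, r_domain, d_marker); pairs with NaN in either source are
    dropped with a logged count.
    """
    common = sorted((set(similarity.ids) & set(distance.ids)) - set(exclude))
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 species common to both matrices after exclusions, got {len(common)}"
        )
    sim = similarity.data.loc[common, common].to_numpy(dtype=float)
    dist = distance.data.loc[common, common].to_numpy(dtype=float)
    rows = []
    dropped = 0
    for i in range(len(common)):
        for j in range(i + 1, len(common)):
            r, d = sim[i, j], dist[i, j]
            if not (np.isfinite(r) and np.isfinite(d)):
                dropped += 1
                continue
            rows.append((common[i], common[j], r, d))
    if dropped:
        logger.warning("dropped %d pair(s) with undefined similarity or distance", dropped)
    table = pd.DataFrame(rows, columns=["id1", "id2", "r_domain", "d_marker"])
    table.attrs["n_species"] = len(common)
    table.attrs["n_dropped"] = dropped
    return table


@dataclass
class ConcordanceResult:
    r: float
    t_statistic: float
    p_value: float
    n: int

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def concordance_r(paired: pd.DataFrame) -> ConcordanceResult:
    """Pearson r of the (r_domain, d_marker) dot cloud with a naive t-test.

    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom, two-sided. See
    the module docstring for why this p-value is optimistic.
    """
    n = len(paired)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    x = paired["r_domain"].to_numpy(dtype=float)
    y = paired["d_marker"].to_numpy(dtype=float)
    for name, col in (("r_domain", x), ("d_marker", y)):
        if np.ptp(col) == 0:
            raise ValueError(f"column {name!r} is constant; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        t = float("inf") if r > 0 else float("-inf")
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    return ConcordanceResult(r=r, t_statistic=float(t), p_value=float(p), n=n)


def mantel_test(
    similarity: SimilarityMatrix,
    distance: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> tuple[float, float, int]:
    """Mantel permutation test of the similarity/distance association.

    Permutes species labels of the distance matrix and recomputes the cloud
    correlation; returns (observed signed r, two-sided p, n_species). The p
    value is ``(1 + #{|r_perm| >= |r_obs|}) / (permutations + 1)``.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    common = sorted((set(similarity.ids) & set(distance.ids)) - set(exclude))
    if len(common) < 3:
        raise ValueError("need >= 3 common species for a Mantel test")
    sim = similarity.data.loc[common, common].to_numpy(dtype=float)
    dist = distance.data.loc[common, common].to_numpy(dtype=float)
    n = len(common)
    iu = np.triu_indices(n, k=1)

    def cloud_r(d: np.ndarray) -> float:
        x, y = sim[iu], d[iu]
        ok = np.isfinite(x) & np.isfinite(y)
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    r_obs = cloud_r(dist)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if abs(cloud_r(dist[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-15:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return r_obs, p, n


def export_dotplot(
    paired: pd.DataFrame, path: str | Path, image: str | Path | None = None
) -> None:
    """Write the dot cloud as plot-ready TSV (id1, id2, x, y); image optional."""
    if paired.empty:
        raise ValueError("paired table is empty")
    out = paired.rename(columns={"r_domain": "x", "d_marker": "y"})
    out.to_csv(path, sep="\t", index=False)
    if image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(out["x"], out["y"], s=4, alpha=0.4)
        ax.set_xlabel("domain-profile correlation (r)")
        ax.set_ylabel("marker pairwise distance")
        fig.tight_layout()
        fig.savefig(image, dpi=150)
        plt.close(fig)
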