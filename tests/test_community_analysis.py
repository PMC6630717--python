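"""Sample clustering (Ward.D2, bootstrap), cluster scoring and PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from domprof import community_analysis as ca
from domprof.containers import DistanceMatrix, DomainCountMatrix, SimilarityMatrix


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.random((n, n)) + 0.1
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(pd.DataFrame(v, index=ids, columns=ids), model="euclidean")


def ward_oracle(values):
    """Brute-force Ward.D2 agglomeration from the original distances.

    Independent route: the between-cluster Ward distance is evaluated
    directly from the closed form
    Delta^2(A,B) = (2|A||B|/(|A|+|B|)) * (mean_{ab} d2 - V_A - V_B),
    V_X = sum_{x,x'} d2 / (2|X|^2), never via the Lance-Williams update.
    """
    n = values.shape[0]
    d2 = values**2
    clusters = {i: [i] for i in range(n)}
    active = list(range(n))
    merges = []
    nxt = n

    def delta(a_members, b_members):
        na, nb = len(a_members), len(b_members)
        between = d2[np.ix_(a_members, b_members)].mean()
        va = d2[np.ix_(a_members, a_members)].sum() / (2 * na**2)
        vb = d2[np.ix_(b_members, b_members)].sum() / (2 * nb**2)
        return math.sqrt(max((2 * na * nb / (na + nb)) * (between - va - vb), 0.0))

    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = sorted((active[i], active[j]))
                cand = (delta(clusters[a], clusters[b]), (a, b))
                if best is None or cand < best:
                    best = cand
        h, (a, b) = best
        merges.append((a, b, h))
        clusters[nxt] = clusters[a] + clusters[b]
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return merges


class TestCorrelationDistance:
    @pytest.mark.parametrize("r,d", [(1.0, 0.0), (-1.0, 2.0), (0.4, 0.6)])
    def test_arithmetic(self, r, d):
        ids = ["a", "b"]
        sim = SimilarityMatrix(pd.DataFrame([[1.0, r], [r, 1.0]], index=ids, columns=ids))
        assert ca.correlation_distance(sim).values()[0, 1] == pytest.approx(d)

    def test_nan_propagates_with_warning(self, caplog):
        ids = list("abc")
        v = np.array([[1, 0.5, np.nan], [0.5, 1, 0.2], [np.nan, 0.2, 1.0]])
        sim = SimilarityMatrix(pd.DataFrame(v, index=ids, columns=ids))
        with caplog.at_level("WARNING"):
            dist = ca.correlation_distance(sim)
        assert np.isnan(dist.values()[0, 2])


class TestHclustWard2:
    def test_two_samples_single_merge(self):
        ids = ["a", "b"]
        dist = DistanceMatrix(
            pd.DataFrame([[0, 0.6], [0.6, 0]], index=ids, columns=ids), model="correlation"
        )
        dend = ca.hclust_ward2(dist)
        assert dend.merges == [(0, 1, pytest.approx(0.6))]

    def test_tight_pairs_merge_first(self):
        ids = list("abcd")
        v = np.array(
            [
                [0.0, 0.1, 5.0, 5.2],
                [0.1, 0.0, 5.1, 5.3],
                [5.0, 5.1, 0.0, 0.2],
                [5.2, 5.3, 0.2, 0.0],
            ]
        )
        dist = DistanceMatrix(pd.DataFrame(v, index=ids, columns=ids), model="euclidean")
        dend = ca.hclust_ward2(dist)
        first_two = {frozenset((dend.merges[0][0], dend.merges[0][1])),
                     frozenset((dend.merges[1][0], dend.merges[1][1]))}
        assert first_two == {frozenset((0, 1)), frozenset((2, 3))}

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_oracle(self, n):
        for seed in range(25):
            dist = random_distance(n, seed=100 * n + seed)
            dend = ca.hclust_ward2(dist)
            expected = ward_oracle(dist.values())
            assert len(dend.merges) == len(expected)
            for got, exp in zip(dend.merges, expected):
                assert got[:2] == exp[:2]
                assert got[2] == pytest.approx(exp[2], abs=1e-9)

    def test_matches_scipy_ward_heights(self):
        """Independent cross-check against scipy's ward linkage on the
        same condensed distances (the ward.D2 convention)."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for seed in range(10):
            dist = random_distance(7, seed=seed)
            dend = ca.hclust_ward2(dist)
            Z = linkage(squareform(dist.values(), checks=False), method="ward")
            assert np.allclose(sorted(m[2] for m in dend.merges), sorted(Z[:, 2]), atol=1e-9)

    def test_heights_monotone(self):
        dend = ca.hclust_ward2(random_distance(10, seed=3))
        heights = [m[2] for m in dend.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_nan_distance_rejected_with_pair(self):
        ids = list("abc")
        v = np.array([[0, 1, np.nan], [1, 0, 1.0], [np.nan, 1, 0]])
        dist = DistanceMatrix(pd.DataFrame(v, index=ids, columns=ids), model="euclidean")
        with pytest.raises(ValueError, match="a.*c"):
            ca.hclust_ward2(dist)


class TestCutClusters:
    @pytest.fixture()
    def dend(self):
        return ca.hclust_ward2(random_distance(6, seed=1))

    def test_k_one_and_k_n(self, dend):
        assert set(ca.cut_clusters(dend, 1).values()) == {0}
        assert len(set(ca.cut_clusters(dend, 6).values())) == 6

    def test_two_pair_example(self):
        ids = list("abcd")
        v = np.array(
            [
                [0.0, 0.1, 5.0, 5.2],
                [0.1, 0.0, 5.1, 5.3],
                [5.0, 5.1, 0.0, 0.2],
                [5.2, 5.3, 0.2, 0.0],
            ]
        )
        dist = DistanceMatrix(pd.DataFrame(v, index=ids, columns=ids), model="euclidean")
        labels = ca.cut_clusters(ca.hclust_ward2(dist), 2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_out_of_range_rejected(self, dend):
        for k in (0, 7):
            with pytest.raises(ValueError):
                ca.cut_clusters(dend, k)


class TestBootstrapSupport:
    def _matrix(self, seed=0, n_rows=40):
        # two sample groups sharing a base profile each, plus small noise
        rng = np.random.default_rng(seed)
        base_left = rng.poisson(8, n_rows)
        base_right = rng.permutation(base_left)
        cols = {}
        for i in range(3):
            cols[f"L{i}"] = base_left + rng.poisson(1, n_rows)
            cols[f"R{i}"] = base_right + rng.poisson(1, n_rows)
        return DomainCountMatrix(pd.DataFrame(cols))

    def test_single_replicate_gives_zero_or_hundred(self):
        dend = ca.bootstrap_support(self._matrix(), B=1, seed=4)
        assert set(dend.support.values()) <= {0.0, 100.0}

    def test_identical_duplicated_columns_get_full_support(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(3, (30, 3))
        data = np.concatenate([base[:, :1], base[:, :1], base[:, 1:]], axis=1)
        m = DomainCountMatrix(pd.DataFrame(data, columns=["dupA", "dupB", "x", "y"]))
        dend = ca.bootstrap_support(m, B=25, seed=6)
        sets = dend.node_leafsets()
        (pair_node,) = [
            node for node, s in sets.items() if s == frozenset({"dupA", "dupB"})
        ]
        assert dend.support[pair_node] == 100.0

    def test_well_separated_groups_high_bp(self):
        dend = ca.bootstrap_support(self._matrix(seed=7), B=100, seed=8)
        sets = dend.node_leafsets()
        left = frozenset({"L0", "L1", "L2"})
        right = frozenset({"R0", "R1", "R2"})
        supports = [dend.support[n] for n, s in sets.items() if s in (left, right)]
        assert supports and min(supports) >= 95.0

    def test_deterministic_per_seed(self):
        m = self._matrix(seed=9)
        a = ca.bootstrap_support(m, B=20, seed=1)
        b = ca.bootstrap_support(m, B=20, seed=1)
        assert a.support == b.support

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            ca.bootstrap_support(self._matrix(), B=0)


class TestClusterMetadataAgreement:
    def test_identical_partitions(self):
        labels = {"a": 0, "b": 0, "c": 1, "d": 1}
        meta = {"a": "x", "b": "x", "c": "y", "d": "y"}
        assert ca.cluster_metadata_agreement(labels, meta) == pytest.approx(1.0)

    def test_singletons_vs_one_group_is_chance(self):
        labels = {s: i for i, s in enumerate("abcd")}
        meta = dict.fromkeys("abcd", "g")
        assert ca.cluster_metadata_agreement(labels, meta) == pytest.approx(0.0)

    def test_matches_contingency_formula(self):
        """Brute-force ARI from the contingency table on a fixed example."""
        from math import comb

        labels = {s: l for s, l in zip("abcdefgh", [0, 0, 0, 1, 1, 1, 2, 2])}
        meta = {s: m for s, m in zip("abcdefgh", "xxyyxzzz")}
        samples = sorted(labels)
        la = [labels[s] for s in samples]
        lb = [meta[s] for s in samples]
        cont = {}
        for x, y in zip(la, lb):
            cont[(x, y)] = cont.get((x, y), 0) + 1
        sum_ij = sum(comb(v, 2) for v in cont.values())
        a_sums = {}
        b_sums = {}
        for (x, y), v in cont.items():
            a_sums[x] = a_sums.get(x, 0) + v
            b_sums[y] = b_sums.get(y, 0) + v
        sum_a = sum(comb(v, 2) for v in a_sums.values())
        sum_b = sum(comb(v, 2) for v in b_sums.values())
        n = comb(len(samples), 2)
        expected = (sum_ij - sum_a * sum_b / n) / (0.5 * (sum_a + sum_b) - sum_a * sum_b / n)
        assert ca.cluster_metadata_agreement(labels, meta) == pytest.approx(expected, abs=1e-9)

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError):
            ca.cluster_metadata_agreement({"a": 0}, {"b": 0})


class TestHeatmapLayout:
    def _matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        return DomainCountMatrix(
            pd.DataFrame(
                rng.poisson(3, (12, 5)),
                index=[f"d{i}" for i in range(12)],
                columns=list("ABCDE"),
            )
        )

    def test_disabled_clustering_keeps_input_order(self):
        m = self._matrix()
        rows, cols, rd, cd = ca.heatmap_layout(m, row_cluster=False, col_cluster=False)
        assert rows == m.row_ids and cols == m.col_ids and rd is None and cd is None

    def test_orders_are_permutations(self):
        m = self._matrix(seed=2)
        rows, cols, rd, cd = ca.heatmap_layout(m)
        assert sorted(rows) == sorted(m.row_ids) and sorted(cols) == sorted(m.col_ids)
        assert rd is not None and cd is not None

    def test_duplicated_columns_adjacent(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(4, (15, 3))
        data = np.concatenate([base, base[:, :1]], axis=1)
        m = DomainCountMatrix(pd.DataFrame(data, columns=["A", "B", "C", "Adup"]))
        _rows, cols, _rd, _cd = ca.heatmap_layout(m)
        assert abs(cols.index("A") - cols.index("Adup")) == 1

    def test_long_table_matches_orders(self):
        m = self._matrix(seed=4)
        rows, cols, *_ = ca.heatmap_layout(m)
        long = ca.heatmap_long_table(m, rows, cols)
        assert len(long) == 12 * 5
        assert long["value"].sum() == m.data.to_numpy().sum()


class TestPCA:
    def test_rank_one_data_single_component(self):
        base = np.arange(4, dtype=float)
        data = np.outer(np.array([1.0, 2.0, 3.0]), base).T  # domains x samples, rank 1
        m = DomainCountMatrix(
            pd.DataFrame(data, columns=["a", "b", "c"]), transform="frequency"
        ) if False else DomainCountMatrix(pd.DataFrame(data.astype(int), columns=["a", "b", "c"]))
        res = ca.pca(m, n_components=2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_samples_one_component_bound(self):
        m = DomainCountMatrix(pd.DataFrame([[1, 2], [3, 1], [0, 4]], columns=["a", "b"]))
        with pytest.raises(ValueError):
            ca.pca(m, n_components=2)
        res = ca.pca(m, n_components=1)
        assert res.n_components == 1

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(6)
        m = DomainCountMatrix(
            pd.DataFrame(rng.poisson(4, (20, 6)), columns=[f"s{i}" for i in range(6)])
        )
        res = ca.pca(m, n_components=5)
        X = m.values().T
        Xc = X - X.mean(axis=0, keepdims=True)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-9)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)

    def test_scores_centered_and_fractions_sorted(self):
        rng = np.random.default_rng(7)
        m = DomainCountMatrix(
            pd.DataFrame(rng.poisson(4, (15, 8)), columns=[f"s{i}" for i in range(8)])
        )
        res = ca.pca(m, n_components=3)
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        f = res.explained_variance_fraction
        assert all(a >= b - 1e-12 for a, b in zip(f, f[1:])) and f.sum() <= 1 + 1e-12

    def test_sign_convention(self):
        rng = np.random.default_rng(8)
        m = DomainCountMatrix(
            pd.DataFrame(rng.poisson(4, (15, 6)), columns=[f"s{i}" for i in range(6)])
        )
        res = ca.pca(m, n_components=3)
        for c in res.loadings.columns:
            col = res.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0


class TestGroupSeparation:
    def test_two_point_masses_perfect(self):
        scores = pd.DataFrame(
            {"PC1": [0.0, 0.0, 10.0, 10.0], "PC2": [0.0] * 4},
            index=list("abcd"),
        )
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        assert ca.group_separation(scores, groups) > 0.95

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(
            rng.normal(size=(40, 2)), columns=["PC1", "PC2"],
            index=[f"s{i}" for i in range(40)],
        )
        groups = {f"s{i}": rng.integers(2) for i in range(40)}
        assert abs(ca.group_separation(scores, groups)) < 0.1

    def test_all_singletons_convention(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0, 2.0]}, index=list("abc"))
        assert ca.group_separation(scores, {"a": 1, "b": 2, "c": 3}) == 0.0

    def test_single_group_rejected(self):
        scores = pd.DataFrame({"PC1": [0.0, 1.0]}, index=list("ab"))
        with pytest.raises(ValueError):
            ca.group_separation(scores, {"a": "g", "b": "g"})

    def test_rank_factors_orders_by_silhouette(self):
        scores = pd.DataFrame(
            {"PC1": [0, 0.1, 5.0, 5.1], "PC2": [0.0] * 4}, index=list("abcd")
        )
        meta = pd.DataFrame(
            {"good": ["x", "x", "y", "y"], "bad": ["x", "y", "x", "y"]}, index=list("abcd")
        )
        ranking = ca.rank_factors(scores, meta, ["good", "bad"])
        assert list(ranking.index) == ["good", "bad"]
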