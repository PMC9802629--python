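"""Consensus clustering: k-means oracle, consensus recount, CDF area,
delta-area model selection, and the Model/Results surface."""

import itertools

import numpy as np
import pytest

from physiotype.cluster import (
    ConsensusKMeans,
    ResampleScheme,
    cdf_area,
    cluster_consensus,
    consensus_matrix,
    delta_areas,
    kmeans_partition,
    select_k,
)


def _two_clouds(n_per=10, sep=10.0, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.5, size=(n_per, dim))
    b = rng.normal(sep, 0.5, size=(n_per, dim))
    return np.vstack([a, b])


class TestKmeansPartition:
    def test_separable_clouds_recovered(self):
        X = _two_clouds()
        labels = kmeans_partition(X, 2, seed=0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k1_constant(self):
        labels = kmeans_partition(_two_clouds(), 1, seed=0)
        assert len(set(labels)) == 1

    def test_wcss_matches_exhaustive_minimum(self):
        """On 8 points, k-means attains the global 2-partition optimum
        found by enumerating all 2^8 assignments."""
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, size=(8, 2))
        X[4:] += 3.0

        def wcss(labels):
            total = 0.0
            for c in set(labels):
                pts = X[np.array(labels) == c]
                total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        brute = min(
            wcss(assign)
            for assign in itertools.product([0, 1], repeat=8)
            if len(set(assign)) == 2
        )
        labels = kmeans_partition(X, 2, seed=0, n_restarts=10)
        assert wcss(labels) == pytest.approx(brute, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            kmeans_partition(np.zeros((3, 2)), 4)
        with pytest.raises(ValueError):
            kmeans_partition(np.empty((0, 2)), 1)

    def test_deterministic_under_seed(self):
        X = _two_clouds(seed=3)
        a = kmeans_partition(X, 2, seed=5)
        b = kmeans_partition(X, 2, seed=5)
        np.testing.assert_array_equal(a, b)


class TestConsensusMatrix:
    def test_duplicate_points_always_coclustered(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.1, 5.2]])
        M, counts = consensus_matrix(X, 2, ResampleScheme(10, 1.0, 0))
        assert M[0, 1] == 1.0

    def test_separable_clouds_binary_consensus(self):
        X = _two_clouds(n_per=6)
        M, _ = consensus_matrix(X, 2, ResampleScheme(20, 0.8, 0))
        within = np.concatenate([M[:6, :6][np.triu_indices(6, 1)],
                                 M[6:, 6:][np.triu_indices(6, 1)]])
        across = M[:6, 6:].ravel()
        assert np.all(within == 1.0)
        assert np.all(across == 0.0)

    def test_matches_independent_recount(self):
        """N=6, 3 resamples with fixed seed ladder: every entry equals a
        plain-Python recount of pair co-occurrences over the stored
        resample partitions."""
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, size=(6, 2))
        scheme = ResampleScheme(n_resamples=3, subsample_fraction=0.8, base_seed=4)
        M, counts = consensus_matrix(X, 2, scheme)

        n, m = 6, int(np.ceil(0.8 * 6))
        together = {}
        sampled = {}
        for r in range(3):
            sub_rng = np.random.default_rng(scheme.base_seed + r)
            idx = sub_rng.choice(n, size=m, replace=False)
            labels = kmeans_partition(X[idx], 2, seed=scheme.base_seed + r,
                                      n_restarts=3)
            for a_pos, a in enumerate(idx):
                for b_pos, b in enumerate(idx):
                    if a < b:
                        sampled[(a, b)] = sampled.get((a, b), 0) + 1
                        if labels[a_pos] == labels[b_pos]:
                            together[(a, b)] = together.get((a, b), 0) + 1
        for a in range(n):
            for b in range(a + 1, n):
                if (a, b) in sampled:
                    expected = together.get((a, b), 0) / sampled[(a, b)]
                else:
                    expected = 0.0
                assert M[a, b] == pytest.approx(expected), (a, b)

    def test_symmetry_range_and_diagonal(self, small_features):
        fm, _ = small_features
        M, _ = consensus_matrix(fm.X[:40], 3, ResampleScheme(10, 0.8, 1))
        np.testing.assert_array_equal(M, M.T)
        assert np.all((M >= 0) & (M <= 1))
        np.testing.assert_array_equal(np.diag(M), 1.0)


class TestCdfArea:
    def test_perfect_two_clustering_area(self):
        M = np.zeros((4, 4))
        M[0, 1] = M[1, 0] = M[2, 3] = M[3, 2] = 1.0
        np.fill_diagonal(M, 1.0)
        _, area = cdf_area(M)
        assert area == pytest.approx(4 / 6)

    def test_all_ones_area_zero(self):
        M = np.ones((5, 5))
        _, area = cdf_area(M)
        assert area == 0.0

    def test_area_matches_riemann_sum(self):
        """Step-sum area equals dense numeric integration of the CDF."""
        rng = np.random.default_rng(0)
        vals = rng.random((7, 7))
        M = (vals + vals.T) / 2
        np.fill_diagonal(M, 1.0)
        (xs, F), area = cdf_area(M)
        entries = M[np.triu_indices(7, 1)]
        grid = np.linspace(0, 1, 10_001)
        cdf_on_grid = (entries[None, :] <= grid[:, None]).mean(axis=1)
        riemann = np.trapezoid(cdf_on_grid, grid)
        assert area == pytest.approx(riemann, abs=1e-3)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            cdf_area(np.ones((1, 1)))


class TestSelectK:
    def test_rule_application(self):
        # delta profile (0.5, 0.30, 0.25, 0.02, 0.01) for k=2..6
        areas = {2: 0.5}
        for k, d in zip(range(3, 7), (0.30, 0.25, 0.02, 0.01)):
            areas[k] = areas[k - 1] * (1 + d)
        assert select_k(areas, threshold=0.10) == 4

    def test_fallback_to_minimum_k(self):
        areas = {2: 0.05, 3: 0.051, 4: 0.052}
        assert select_k(areas, threshold=0.10) == 2

    def test_boundary_tie_keeps_smaller_k(self):
        areas = {2: 1.0, 3: 1.25}  # delta exactly at threshold 0.25
        assert select_k(areas, threshold=0.25) == 2

    def test_delta_areas_empty_rejected(self):
        with pytest.raises(ValueError):
            delta_areas({})


class TestClusterConsensus:
    def test_perfect_clouds_consensus_one(self):
        X = _two_clouds(n_per=5)
        M, _ = consensus_matrix(X, 2, ResampleScheme(10, 0.8, 0))
        labels = kmeans_partition(X, 2, seed=0)
        cc = cluster_consensus(M, labels)
        assert all(v == 1.0 for v in cc.values())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        M = rng.random((8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        labels = np.array([0, 0, 1, 1, 1, 2, 2, 2])
        cc1 = cluster_consensus(M, labels)
        relabeled = np.array([2, 2, 0, 0, 0, 1, 1, 1])
        cc2 = cluster_consensus(M, relabeled)
        assert sorted(cc1.values()) == pytest.approx(sorted(cc2.values()))

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(2)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        cc = cluster_consensus(M, labels)
        expected0 = np.mean([M[0, 1], M[0, 2], M[1, 2]])
        expected1 = np.mean([M[3, 4], M[3, 5], M[4, 5]])
        assert cc[0] == pytest.approx(expected0)
        assert cc[1] == pytest.approx(expected1)

    def test_singleton_reports_one_with_warning(self):
        M = np.eye(3)
        with pytest.warns(UserWarning, match="singleton"):
            cc = cluster_consensus(M, np.array([0, 1, 1]))
        assert cc[0] == 1.0


class TestConsensusKMeansModel:
    def test_area_nondecreasing_in_k(self, small_features):
        fm, _ = small_features
        res = ConsensusKMeans(
            fm.X[:80], k_range=(2, 3, 4, 5), scheme=ResampleScheme(20, 0.8, 0)
        ).fit()
        areas = [res.areas[k] for k in sorted(res.areas)]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(areas, areas[1:]))

    def test_summary_shape_and_labels(self, small_features):
        fm, _ = small_features
        res = ConsensusKMeans(
            fm.X[:60], k_range=(2, 3, 4), scheme=ResampleScheme(10, 0.8, 0)
        ).fit()
        assert set(res.summary().columns) >= {"k", "cdf_area", "delta_area"}
        assert len(np.unique(res.labels)) == res.selected_k

    def test_resample_stability(self, small_features):
        """Doubling the number of resamples moves consensus entries only
        within Monte-Carlo noise (<= 0.1 for the bulk of entries)."""
        fm, _ = small_features
        X = fm.X[:80]
        M1, _ = consensus_matrix(X, 4, ResampleScheme(40, 0.8, 0))
        M2, _ = consensus_matrix(X, 4, ResampleScheme(80, 0.8, 0))
        diffs = np.abs(M1 - M2)[np.triu_indices(80, 1)]
        assert np.quantile(diffs, 0.95) <= 0.1
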