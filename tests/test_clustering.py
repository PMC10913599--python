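from itertools import product

import numpy as np
import pytest

from statedyn._errors import ConfigurationError, InfeasibleKError
from statedyn.clustering import (
    METHODS,
    StatePartition,
    atomize_reassign,
    cluster,
    cosine_similarity,
    gev_total,
    wcss,
    worst_cluster_crs,
    worst_cluster_gev,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_bipartition_rss(x):
    """Global optimum of the 2-means objective by exhaustive bipartition."""
    t = x.shape[0]
    best = np.inf
    for bits in product([0, 1], repeat=t - 1):
        labels = np.array((0,) + bits)
        if labels.min() == labels.max():
            continue
        rss = 0.0
        for ell in (0, 1):
            pts = x[labels == ell]
            rss += np.sum((pts - pts.mean(axis=0)) ** 2)
        best = min(best, rss)
    return best


def oracle_cos(u, v):
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def oracle_gev_per_cluster(x, labels1, centroids, sigma):
    """Direct loop evaluation of the per-cluster GEV definition."""
    k = centroids.shape[0]
    denom = float(np.sum(np.asarray(sigma) ** 2))
    out = []
    for ell in range(1, k + 1):
        acc = 0.0
        for t in range(x.shape[0]):
            if labels1[t] == ell:
                acc += oracle_cos(x[t], centroids[ell - 1]) ** 2 * sigma[t] ** 2
        out.append(acc / denom)
    return np.array(out)


def oracle_crs(x, labels1, centroids):
    k = centroids.shape[0]
    out = []
    for ell in range(1, k + 1):
        acc = 0.0
        for t in range(x.shape[0]):
            if labels1[t] == ell:
                acc += oracle_cos(x[t], centroids[ell - 1])
        out.append(acc)
    return np.array(out)


def make_partition(x, labels1, method="kmeans"):
    k = int(np.max(labels1))
    centroids = np.vstack(
        [x[np.asarray(labels1) == ell].mean(axis=0) for ell in range(1, k + 1)]
    )
    return StatePartition(
        labels=np.asarray(labels1), centroids=centroids, method=method, K=k
    )


# ---------------------------------------------------------------------------


class TestCosineSimilarity:
    def test_parallel(self):
        assert cosine_similarity([1, 0], [1, 0]) == 1.0

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == 0.0

    def test_antiparallel(self):
        assert cosine_similarity([1, 0], [-1, 0]) == -1.0

    def test_zero_vector_raises(self):
        with pytest.raises(ConfigurationError):
            cosine_similarity([0, 0], [1, 0])


class TestClusterDispatch:
    @pytest.mark.parametrize("method", METHODS)
    def test_blobs_recovered(self, blobs, method):
        x, truth = blobs
        part = cluster(x, 2, method, seed=0)
        a = part.labels[truth == 0]
        b = part.labels[truth == 1]
        assert len(set(a)) == 1 and len(set(b)) == 1 and a[0] != b[0]

    @pytest.mark.parametrize("method", METHODS)
    def test_determinism(self, blobs, method):
        x, _ = blobs
        p1 = cluster(x, 2, method, seed=5)
        p2 = cluster(x, 2, method, seed=5)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        np.testing.assert_array_equal(p1.centroids, p2.centroids)

    def test_kmeans_matches_exhaustive_bipartition(self, blobs):
        x, _ = blobs
        x = x[::2]  # 10 points keeps the 2^9 oracle cheap
        part = cluster(x, 2, "kmeans", seed=0)
        np.testing.assert_allclose(
            wcss(x, part), brute_force_bipartition_rss(x), rtol=1e-10
        )

    def test_kmeans_rss_at_least_global_optimum(self, rng):
        for _ in range(5):
            x = rng.standard_normal((9, 3))
            part = cluster(x, 2, "kmeans", seed=int(rng.integers(1 << 30)))
            assert wcss(x, part) >= brute_force_bipartition_rss(x) - 1e-9

    def test_kmeans_finds_optimum_on_blobs_most_seeds(self, blobs):
        x, _ = blobs
        x = x[::2]
        opt = brute_force_bipartition_rss(x)
        hits = sum(
            np.isclose(wcss(x, cluster(x, 2, "kmeans", seed=s)), opt)
            for s in range(20)
        )
        assert hits >= 18  # >= 90% of seeds

    def test_kmeans_rss_monotone(self, small_study):
        x = small_study.sessions[0][0].data
        part = cluster(x, 4, "kmeans", seed=1)
        trace = np.array(part.objective_trace)
        assert len(trace) >= 1
        assert np.all(np.diff(trace) <= 1e-9)

    def test_kmedoids_each_point_own_cluster(self):
        x = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        part = cluster(x, 3, "kmedoids", seed=0)
        assert sorted(part.labels) == [1, 2, 3]
        assert {tuple(c) for c in part.centroids} == {tuple(r) for r in x}

    def test_kmedoids_centroids_are_data_rows(self, small_study):
        x = small_study.sessions[0][0].data
        part = cluster(x, 3, "kmedoids", seed=2)
        rows = {tuple(np.round(r, 12)) for r in x}
        for c in part.centroids:
            assert tuple(np.round(c, 12)) in rows

    @pytest.mark.parametrize(
        "method", ["kmeans", "ward", "aahc", "taahc", "bisecting_kmeans"]
    )
    def test_centroids_are_member_means(self, small_study, method):
        x = small_study.sessions[0][0].data
        part = cluster(x, 3, method, seed=3)
        for ell in range(1, 4):
            np.testing.assert_allclose(
                part.centroids[ell - 1],
                x[part.labels == ell].mean(axis=0),
                atol=1e-10,
            )

    @pytest.mark.parametrize("method", ["aahc", "taahc"])
    def test_atomize_step_count_is_t_minus_k(self, blobs, method):
        x, _ = blobs
        part = cluster(x, 2, method, seed=0)
        assert part.n_atomize_steps == x.shape[0] - 2

    def test_gmm_loglik_nondecreasing(self, small_study):
        x = small_study.sessions[1][0].data
        part = cluster(x, 3, "gmm", seed=4)
        trace = np.array(part.objective_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-8)

    def test_infeasible_k_raises(self):
        x = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(InfeasibleKError):
            cluster(x, 3, "kmeans", seed=0)

    def test_k_above_t_raises(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(InfeasibleKError):
            cluster(x, 3, "kmeans", seed=0)

    def test_unknown_method_raises(self, blobs):
        with pytest.raises(ConfigurationError):
            cluster(blobs[0], 2, "dbscan", seed=0)

    def test_every_state_nonempty(self, small_study):
        x = small_study.sessions[2][1].data
        for method in METHODS:
            part = cluster(x, 4, method, seed=9)
            assert set(np.unique(part.labels)) == {1, 2, 3, 4}


class TestWorstCluster:
    def test_gev_orthogonal_cluster_is_worst(self):
        # cluster 1 parallel to centroid, cluster 2 orthogonal to its centroid
        x = np.array([[1.0, 0.0], [2.0, 0.0], [1.0, 1.0], [-1.0, -1.0]])
        centroids = np.array([[1.5, 0.0], [1.0, -1.0]])
        part = StatePartition(
            labels=np.array([1, 1, 2, 2]),
            centroids=centroids,
            method="kmeans",
            K=2,
        )
        sigma = np.ones(4)
        assert worst_cluster_gev(x, part, sigma) == 2

    def test_gev_tie_breaks_to_smallest_index(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        part = make_partition(x, [1, 2])
        assert worst_cluster_gev(x, part, np.ones(2)) == 1

    def test_gev_matches_brute_force(self, rng):
        x = rng.standard_normal((4, 2))
        labels = np.array([1, 1, 2, 2])
        part = make_partition(x, labels)
        sigma = rng.uniform(0.5, 2.0, size=4)
        ours = worst_cluster_gev(x, part, sigma)
        oracle = (
            int(np.argmin(oracle_gev_per_cluster(x, labels, part.centroids, sigma)))
            + 1
        )
        assert ours == oracle

    def test_crs_singleton_vs_coherent_cluster(self):
        # singleton CRS = cos(x, x) = 1 < m for m coherent parallel points
        x = np.array([[1.0, 1.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        part = StatePartition(
            labels=np.array([1, 2, 2, 2]),
            centroids=np.array([[1.0, 1.0], [2.0, 0.0]]),
            method="taahc",
            K=2,
        )
        assert worst_cluster_crs(x, part) == 1

    def test_crs_matches_brute_force(self, rng):
        x = rng.standard_normal((5, 3))
        labels = np.array([1, 2, 2, 3, 3])
        part = make_partition(x, labels)
        ours = worst_cluster_crs(x, part)
        oracle = int(np.argmin(oracle_crs(x, labels, part.centroids))) + 1
        assert ours == oracle


class TestAtomizeReassign:
    def test_parallel_points_join_parallel_survivors(self):
        x = np.array(
            [[1.0, 0.0], [2.0, 0.0], [0.0, 1.0], [0.0, 2.0], [3.0, 0.0], [0.0, 3.0]]
        )
        part = make_partition(x, [1, 1, 2, 2, 3, 3])
        # cluster 3 holds (3,0) and (0,3): each parallel to one survivor
        out = atomize_reassign(x, part, worst=3)
        assert out.K == 2
        np.testing.assert_array_equal(out.labels, [1, 1, 2, 2, 1, 2])

    def test_hand_traced_centroids(self):
        x = np.array(
            [
                [1.0, 0.0],
                [2.0, 0.0],
                [0.0, 1.0],
                [0.0, 2.0],
                [3.0, 0.1],
                [0.1, 3.0],
            ]
        )
        part = make_partition(x, [1, 1, 2, 2, 3, 3])
        out = atomize_reassign(x, part, worst=3)
        np.testing.assert_array_equal(out.labels, [1, 1, 2, 2, 1, 2])
        np.testing.assert_allclose(out.centroids[0], [2.0, 0.1 / 3])
        np.testing.assert_allclose(out.centroids[1], [0.1 / 3, 2.0])

    def test_cluster_count_decreases_by_one(self, rng):
        x = rng.standard_normal((9, 3))
        part = make_partition(x, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        out = atomize_reassign(x, part, worst=2)
        assert out.K == part.K - 1
        assert len(out.labels) == 9
        assert set(np.unique(out.labels)) == {1, 2}

    def test_single_cluster_cannot_atomize(self, rng):
        x = rng.standard_normal((4, 2))
        part = make_partition(x, [1, 1, 1, 1])
        with pytest.raises(ConfigurationError):
            atomize_reassign(x, part, worst=1)


class TestGevTotalAndWcss:
    def test_gev_total_parallel_is_one(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
        part = make_partition(x, [1, 1, 2, 2])
        np.testing.assert_allclose(gev_total(x, part, np.ones(4)), 1.0)

    def test_gev_total_orthogonal_is_zero(self):
        x = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]])
        centroids = np.array([[1.0, -1.0], [1.0, 1.0]])
        part = StatePartition(
            labels=np.array([1, 1, 2, 2]),
            centroids=centroids,
            method="kmeans",
            K=2,
        )
        np.testing.assert_allclose(gev_total(x, part, np.ones(4)), 0.0, atol=1e-15)

    def test_gev_total_matches_brute_force(self, rng):
        x = rng.standard_normal((4, 3))
        labels = np.array([1, 2, 1, 2])
        part = make_partition(x, labels)
        sigma = rng.uniform(0.5, 2.0, size=4)
        np.testing.assert_allclose(
            gev_total(x, part, sigma),
            oracle_gev_per_cluster(x, labels, part.centroids, sigma).sum(),
        )

    def test_gev_total_unit_sigma_simplification(self, rng):
        x = rng.standard_normal((8, 4))
        labels = np.array([1, 1, 2, 2, 1, 2, 1, 2])
        part = make_partition(x, labels)
        cos2 = [
            oracle_cos(x[t], part.centroids[labels[t] - 1]) ** 2 for t in range(8)
        ]
        np.testing.assert_allclose(
            gev_total(x, part, np.ones(8)), np.mean(cos2)
        )

    def test_wcss_zero_when_points_equal_centroids(self):
        x = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0], [0.0, 2.0]])
        part = make_partition(x, [1, 1, 2, 2])
        assert wcss(x, part) == 0.0

    def test_wcss_hand_value(self):
        x = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 5.0], [0.0, 7.0]])
        part = make_partition(x, [1, 1, 2, 2])
        # cluster 1: points 0 and 2 in 1-D -> 1 + 1 = 2; cluster 2 likewise
        np.testing.assert_allclose(wcss(x, part), 4.0)

    def test_wcss_nonincreasing_in_k_for_bisecting(self, small_study):
        x = small_study.sessions[0][0].data
        values = [
            wcss(x, cluster(x, k, "bisecting_kmeans", seed=0)) for k in range(2, 7)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_gev_requires_positive_sigma(self, rng):
        x = rng.standard_normal((4, 3))
        part = make_partition(x, [1, 1, 2, 2])
        with pytest.raises(ConfigurationError):
            gev_total(x, part, np.zeros(4))
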