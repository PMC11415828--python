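import numpy as np
import pytest

from scintruler.clustering import ClusterAssignment
from scintruler.distances import (
    euclidean_distances,
    knn_distance_arrays,
    sample_pools,
)
from scintruler.preprocess import NormalizedMatrix


def make_assignment(fine_size=80, source_sizes=(1000, 1000, 1000)):
    """K sources; the first fine cluster sits inside source 1."""
    sources, fine, broad = [], [], []
    for k, n in enumerate(source_sizes):
        sources += [f"s{k + 1}"] * n
        broad += [0] * n
        if k == 0:
            fine += ["s1|b0|f0"] * fine_size + ["s1|b0|f1"] * (n - fine_size)
        else:
            fine += [f"s{k + 1}|b0|f0"] * n
    n_total = sum(source_sizes)
    return ClusterAssignment(
        cell_ids=np.array([f"c{i}" for i in range(n_total)], dtype=object),
        source=np.array(sources, dtype=object),
        broad=np.array(broad),
        fine=np.array(fine, dtype=object),
        rng_seed=0,
    )


class TestSamplePools:
    def test_default_sizes_three_sources(self):
        assign = make_assignment(fine_size=80, source_sizes=(1000, 1000, 1000))
        q, w, b = sample_pools(assign, "s1|b0|f0", rng_seed=1)
        assert len(q) == 20
        assert len(w) == 500
        assert len(b) == 1000  # 500 per other source, K=3

    def test_query_capped_at_fine_size(self):
        assign = make_assignment(fine_size=12, source_sizes=(400, 400))
        q, _, _ = sample_pools(assign, "s1|b0|f0", rng_seed=1)
        assert len(q) == 12
        assert set(assign.fine[q]) == {"s1|b0|f0"}

    def test_within_capped_at_availability(self):
        assign = make_assignment(fine_size=100, source_sizes=(400, 400))
        _, w, _ = sample_pools(assign, "s1|b0|f0", rng_seed=1)
        assert len(w) == 300  # 400 - 100 available

    def test_pools_exclude_wrong_cells(self):
        assign = make_assignment(fine_size=50, source_sizes=(600, 600, 600))
        q, w, b = sample_pools(assign, "s1|b0|f0", rng_seed=3)
        assert set(assign.fine[w]).isdisjoint({"s1|b0|f0"})
        assert set(assign.source[w]) == {"s1"}
        assert "s1" not in set(assign.source[b])
        assert len(set(q) | set(w) | set(b)) == len(q) + len(w) + len(b)

    def test_between_stratified_across_sources(self):
        assign = make_assignment(fine_size=50, source_sizes=(600, 600, 600))
        _, _, b = sample_pools(assign, "s1|b0|f0", n_between_per_source=200, rng_seed=3)
        srcs, counts = np.unique(assign.source[b], return_counts=True)
        assert sorted(srcs) == ["s2", "s3"]
        np.testing.assert_array_equal(counts, [200, 200])

    def test_fine_cluster_covering_source_errors(self):
        assign = make_assignment(fine_size=400, source_sizes=(400, 400))
        with pytest.raises(ValueError, match="within-pool"):
            sample_pools(assign, "s1|b0|f0", rng_seed=0)

    def test_reproducible(self):
        assign = make_assignment()
        a = sample_pools(assign, "s1|b0|f0", rng_seed=5)
        b = sample_pools(assign, "s1|b0|f0", rng_seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


def cosine_matrix(X):
    X = X / np.linalg.norm(X, axis=0)
    g, c = X.shape
    return NormalizedMatrix(X, [f"g{i}" for i in range(g)], [f"c{i}" for i in range(c)], "cosine")


class TestEuclideanDistances:
    def test_orthogonal_unit_vectors(self):
        m = cosine_matrix(np.eye(2))
        d = euclidean_distances(np.array([0]), np.array([1]), m)
        np.testing.assert_allclose(d, [[np.sqrt(2)]])

    def test_identical_columns_zero(self):
        X = np.array([[1.0, 1.0, 2.0], [2.0, 2.0, 1.0]])
        m = cosine_matrix(X)
        d = euclidean_distances(np.array([0]), np.array([1, 2]), m)
        assert d[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 2.0, size=(9, 9))
        m = cosine_matrix(X)
        queries, pool = np.array([0, 1, 2, 3, 4]), np.array([5, 6, 7, 8])
        d = euclidean_distances(queries, pool, m)
        Xn = X / np.linalg.norm(X, axis=0)
        for a, i in enumerate(queries):
            for b, j in enumerate(pool):
                expected = np.sqrt(((Xn[:, i] - Xn[:, j]) ** 2).sum())
                assert d[a, b] == pytest.approx(expected, abs=1e-10)

    def test_overlapping_sets_rejected(self):
        m = cosine_matrix(np.eye(3))
        with pytest.raises(ValueError, match="disjoint"):
            euclidean_distances(np.array([0, 1]), np.array([1, 2]), m)

    def test_requires_cosine_stage(self):
        m = NormalizedMatrix(np.eye(2), ["g0", "g1"], ["c0", "c1"], "lognorm")
        with pytest.raises(ValueError, match="cosine"):
            euclidean_distances(np.array([0]), np.array([1]), m)


class TestKnnDistanceArrays:
    def test_default_array_length_is_300(self):
        rng = np.random.default_rng(1)
        arrays = knn_distance_arrays(rng.random((20, 500)), rng.random((20, 1000)), k_nn=15)
        assert len(arrays.d_within) == 300
        assert len(arrays.d_between) == 300

    def test_fewer_queries_shorter_arrays(self):
        rng = np.random.default_rng(1)
        arrays = knn_distance_arrays(rng.random((5, 100)), rng.random((5, 100)), k_nn=15)
        assert len(arrays.d_within) == 75

    def test_smallest_k_selected(self):
        dw = np.array([[3.0, 1.0, 2.0]])
        db = np.array([[9.0, 7.0, 8.0]])
        arrays = knn_distance_arrays(dw, db, k_nn=2)
        np.testing.assert_array_equal(arrays.d_within, [1.0, 2.0])
        np.testing.assert_array_equal(arrays.d_between, [7.0, 8.0])

    def test_pool_order_irrelevant(self):
        rng = np.random.default_rng(2)
        dw, db = rng.random((8, 60)), rng.random((8, 90))
        a = knn_distance_arrays(dw, db, k_nn=10)
        perm_w = dw[:, rng.permutation(60)]
        perm_b = db[:, rng.permutation(90)]
        b = knn_distance_arrays(perm_w, perm_b, k_nn=10)
        np.testing.assert_allclose(np.sort(a.d_within), np.sort(b.d_within))
        np.testing.assert_allclose(np.sort(a.d_between), np.sort(b.d_between))

    def test_small_pool_reduces_k_for_both(self, caplog):
        rng = np.random.default_rng(3)
        with caplog.at_level("WARNING"):
            arrays = knn_distance_arrays(rng.random((4, 8)), rng.random((4, 50)), k_nn=15)
        assert arrays.k_nn == 8
        assert len(arrays.d_within) == len(arrays.d_between) == 32
        assert "k=8" in caplog.text

    def test_exchangeable_equal_pools_unbiased(self):
        # both pools iid from one population and of equal size: the mean
        # difference of the k-NN arrays has expectation ~0
        rng = np.random.default_rng(42)
        diffs = []
        for _ in range(60):
            dw = rng.exponential(size=(15, 200))
            db = rng.exponential(size=(15, 200))
            arrays = knn_distance_arrays(dw, db, k_nn=10)
            diffs.append(arrays.d_between.mean() - arrays.d_within.mean())
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se
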