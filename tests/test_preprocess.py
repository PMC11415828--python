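import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scintruler.preprocess import (
    NormalizedMatrix,
    cosine_normalize,
    log_normalize,
    pca_embed,
    select_hvgs,
)

from conftest import counts_matrix


def lognorm_of(values):
    return log_normalize(counts_matrix(values), scale_total=1e4)


class TestLogNormalize:
    def test_closed_form(self):
        m = counts_matrix([[2], [0], [2]])
        out = log_normalize(m, scale_total=4)
        np.testing.assert_allclose(
            out.values.toarray().ravel(), [np.log1p(2), 0.0, np.log1p(2)]
        )
        assert out.stage == "lognorm"

    def test_equal_columns_stay_equal(self):
        m = counts_matrix([[3, 3], [1, 1]])
        out = log_normalize(m, scale_total=8).values.toarray()
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_depth_removed(self):
        # two cells proportional to (1, 0) at different depths normalize identically
        m = counts_matrix([[10, 1], [0, 0]])
        out = log_normalize(m, scale_total=10).values.toarray()
        np.testing.assert_allclose(out[:, 0], [np.log1p(10), 0.0])
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            log_normalize(counts_matrix([[1, 0], [1, 0]]))

    def test_wrong_stage_rejected(self):
        ln = lognorm_of([[1.0], [2.0]])
        with pytest.raises(ValueError, match="counts-stage"):
            log_normalize(ln)  # type: ignore[arg-type]


class TestCosineNormalize:
    def test_closed_form(self):
        nm = NormalizedMatrix(np.array([[3.0], [4.0]]), ["g0", "g1"], ["c0"], "lognorm")
        out = cosine_normalize(nm)
        np.testing.assert_allclose(out.values.ravel(), [0.6, 0.8])
        assert out.stage == "cosine"

    def test_unit_column_unchanged(self):
        col = np.array([[0.6], [0.8]])
        nm = NormalizedMatrix(col, ["g0", "g1"], ["c0"], "lognorm")
        np.testing.assert_allclose(cosine_normalize(nm).values, col)

    def test_output_norms_are_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0.1, 5, size=(30, 10))
        nm = NormalizedMatrix(X, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(10)], "lognorm")
        norms = np.linalg.norm(cosine_normalize(nm).values, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)

    def test_zero_column_names_cell(self):
        nm = NormalizedMatrix(
            np.array([[1.0, 0.0], [1.0, 0.0]]), ["g0", "g1"], ["good", "bad"], "lognorm"
        )
        with pytest.raises(ValueError, match="bad"):
            cosine_normalize(nm)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        X = np.array([[1.0, 2.0], [3.0, 0.5], [0.2, 1.1]])
        base = cosine_normalize(NormalizedMatrix(X.copy(), list("abc"), ["x", "y"], "lognorm"))
        scaled_X = X.copy()
        scaled_X[:, 0] *= c
        scaled = cosine_normalize(NormalizedMatrix(scaled_X, list("abc"), ["x", "y"], "lognorm"))
        np.testing.assert_allclose(scaled.values[:, 0], base.values[:, 0], atol=1e-10)

    def test_unit_vectors_distance_bounded_by_two(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 50))
        X /= np.linalg.norm(X, axis=0)
        d = np.linalg.norm(X[:, :, None] - X[:, None, :], axis=0)
        assert d.max() <= 2.0 + 1e-12


class TestSelectHVGs:
    def test_variable_gene_ranked_first(self):
        X = np.ones((3, 6))
        X[1] = [0, 5, 0, 5, 0, 5]  # only g1 varies
        nm = NormalizedMatrix(X, ["g0", "g1", "g2"], [f"c{i}" for i in range(6)], "lognorm")
        assert select_hvgs(nm, 1)[0] == "g1"

    def test_all_genes_returned(self):
        nm = NormalizedMatrix(np.random.default_rng(0).uniform(size=(4, 5)),
                              list("dcba"), [f"c{i}" for i in range(5)], "lognorm")
        assert set(select_hvgs(nm, 4)) == set("abcd")

    def test_tie_broken_by_gene_id(self):
        # two genes with identical columns -> identical statistics
        X = np.array([[1.0, 3.0], [1.0, 3.0], [0.0, 0.0]])
        nm = NormalizedMatrix(X, ["zz", "aa", "mm"], ["c0", "c1"], "lognorm")
        assert list(select_hvgs(nm, 1)) == ["aa"]

    @pytest.mark.parametrize("n_top", [0, -2])
    def test_nonpositive_n_top(self, n_top):
        nm = NormalizedMatrix(np.ones((2, 2)), ["a", "b"], ["x", "y"], "lognorm")
        with pytest.raises(ValueError):
            select_hvgs(nm, n_top)


class TestPCAEmbed:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 40)
        X = np.vstack([2 * t, -t])  # cells on a line in 2-gene space
        nm = NormalizedMatrix(X, ["g0", "g1"], [f"c{i}" for i in range(40)], "lognorm")
        emb = pca_embed(nm, None, 1)
        # a 1-d embedding of collinear data preserves all pairwise structure
        order = np.argsort(emb.coordinates[:, 0])
        assert (np.all(order == np.arange(40)) or np.all(order == np.arange(40)[::-1]))

    def test_duplicated_cells_get_identical_rows(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(5, 8))
        Xd = np.hstack([X, X])
        nm = NormalizedMatrix(Xd, [f"g{i}" for i in range(5)],
                              [f"c{i}" for i in range(16)], "lognorm")
        emb = pca_embed(nm, None, 2)
        np.testing.assert_allclose(emb.coordinates[:8], emb.coordinates[8:], atol=1e-8)

    def test_two_gene_eigenvector_oracle(self):
        # correlated 2-gene data: after standardization the leading eigenvector
        # of the correlation matrix is (1,1)/sqrt(2)
        rng = np.random.default_rng(3)
        z = rng.normal(size=500)
        X = np.vstack([z + 0.1 * rng.normal(size=500), z + 0.1 * rng.normal(size=500)])
        nm = NormalizedMatrix(X, ["g0", "g1"], [f"c{i}" for i in range(500)], "lognorm")
        emb = pca_embed(nm, None, 1)
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        expected = Xs.T @ (np.ones(2) / np.sqrt(2))
        corr = np.corrcoef(emb.coordinates[:, 0], expected)[0, 1]
        assert abs(corr) > 0.999
        # sign convention: largest loading positive => scores correlate positively
        assert corr > 0

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(20, 30))
        nm = NormalizedMatrix(X, [f"g{i}" for i in range(20)],
                              [f"c{i}" for i in range(30)], "lognorm")
        a = pca_embed(nm, None, 5).coordinates
        b = pca_embed(nm, None, 5).coordinates
        np.testing.assert_array_equal(a, b)

    def test_rank_exceeded_rejected(self):
        nm = NormalizedMatrix(np.ones((3, 4)), list("abc"), list("wxyz"), "lognorm")
        with pytest.raises(ValueError, match="rank"):
            pca_embed(nm, None, 4)
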