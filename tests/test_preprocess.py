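"""Normalization, summaries, embeddings and exact kNN graphs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from batcheval import (IntegratedDataset, knn_neighbors, minmax_log_normalize,
                       pca_embed, per_cell_total_counts,
                       per_gene_mean_variance, umap_embed)
from batcheval.preprocess import exact_knn


def _ds(matrix, batch=None):
    matrix = np.asarray(matrix, dtype=float)
    n, g = matrix.shape
    return IntegratedDataset(
        matrix=matrix, obs_ids=[f"c{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        batch=np.asarray(batch if batch is not None else ["b0"] * n, dtype=object))


class TestNormalize:
    def test_hand_values(self):
        out = minmax_log_normalize(np.array([[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(out[0], [0.0, np.log1p(0.5), np.log1p(1.0)],
                                   atol=1e-12)

    def test_bounds_at_extremes(self):
        m = np.array([[1.0, 3.0], [2.0, 7.0]])
        out = minmax_log_normalize(m)
        assert out.min() == 0.0                       # x = x_min
        assert out.max() == pytest.approx(np.log1p(1.0))  # x = x_max

    def test_constant_matrix_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_log_normalize(np.full((3, 3), 4.0))
        assert (out == 0.0).all()

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2,
                    max_size=30, unique=True))
    def test_monotone_and_bounded(self, values):
        x = np.array(values)[None, :]
        out = minmax_log_normalize(x)[0]
        order = np.argsort(x[0])
        assert (np.diff(out[order]) >= 0).all()
        assert out.min() >= 0.0 and out.max() <= np.log(2) + 1e-12


class TestSummaries:
    def test_row_sums(self):
        ds = _ds([[1, 2], [3, 4]])
        np.testing.assert_array_equal(per_cell_total_counts(ds), [3, 7])
        np.testing.assert_array_equal(
            per_cell_total_counts(_ds([[0, 0]])), [0])

    def test_totals_invariant_to_gene_order(self, rng):
        m = rng.integers(0, 9, size=(5, 6)).astype(float)
        perm = rng.permutation(6)
        np.testing.assert_array_equal(per_cell_total_counts(_ds(m)),
                                      per_cell_total_counts(_ds(m[:, perm])))

    def test_mean_variance_ddof0(self):
        ds = _ds([[2.0], [2.0], [2.0]])
        mean, var = per_gene_mean_variance(ds, by_batch=False)
        assert mean[0] == 2.0 and var[0] == 0.0
        mean, var = per_gene_mean_variance(_ds([[0.0], [2.0]]), by_batch=False)
        assert mean[0] == 1.0 and var[0] == 1.0  # population variance

    def test_shift_moves_mean_not_variance(self, rng):
        m = rng.normal(10, 2, size=(20, 4)) ** 2
        by = per_gene_mean_variance(_ds(np.vstack([m, m + 5.0]),
                                        batch=["a"] * 20 + ["b"] * 20))
        np.testing.assert_allclose(by["b"][0], by["a"][0] + 5.0, atol=1e-9)
        np.testing.assert_allclose(by["b"][1], by["a"][1], atol=1e-9)


class TestPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=10)
        v = np.abs(rng.normal(size=6))
        ds = _ds(np.abs(np.outer(u, v)))
        ds.layers["normalized"] = ds.matrix - ds.matrix.mean(0)
        scores = pca_embed(ds, n_components=3, layer="normalized")
        var = scores.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_duplicated_observations_identical_scores(self, rng):
        m = np.abs(rng.normal(size=(8, 5)))
        ds = _ds(np.vstack([m, m]))
        scores = pca_embed(ds, n_components=2)
        np.testing.assert_allclose(scores[:8], scores[8:], atol=1e-10)

    def test_deterministic(self, rng):
        m = np.abs(rng.normal(size=(12, 6)))
        s1 = pca_embed(_ds(m), n_components=3, seed=0)
        s2 = pca_embed(_ds(m), n_components=3, seed=0)
        np.testing.assert_array_equal(s1, s2)

    def test_too_many_components(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_embed(_ds(np.ones((4, 3))), n_components=3)


class TestUMAP:
    def test_blobs_stay_separable_and_seeded(self, rng):
        a = rng.normal(0, 0.3, size=(60, 8))
        b = rng.normal(8, 0.3, size=(60, 8))
        ds = _ds(np.abs(np.vstack([a, b])) + 1)
        pca_embed(ds, n_components=5)
        coords = umap_embed(ds, n_neighbors=10, seed=0)
        lab = np.array([0] * 60 + [1] * 60)
        cent = np.array([coords[lab == i].mean(0) for i in (0, 1)])
        d = np.linalg.norm(coords[:, None, :] - cent[None], axis=2)
        acc = (d.argmin(1) == lab).mean()
        assert max(acc, 1 - acc) > 0.95
        ds2 = _ds(ds.matrix)
        pca_embed(ds2, n_components=5)
        np.testing.assert_array_equal(coords, umap_embed(ds2, n_neighbors=10, seed=0))

    def test_too_few_points(self):
        ds = _ds(np.abs(np.random.default_rng(0).normal(size=(10, 4))))
        pca_embed(ds, n_components=3)
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_embed(ds, n_neighbors=50)


class TestKNN:
    def test_collinear_hand_case(self):
        ds = _ds(np.ones((3, 1)))
        ds.embeddings["e"] = np.array([[0.0], [1.0], [10.0]])
        g = knn_neighbors(ds, "e", k=1)
        np.testing.assert_array_equal(g.indices[:, 0], [1, 0, 1])

    def test_full_graph(self, rng):
        ds = _ds(np.ones((5, 1)))
        ds.embeddings["e"] = rng.normal(size=(5, 2))
        g = knn_neighbors(ds, "e", k=4)
        for i in range(5):
            assert set(g.indices[i]) == set(range(5)) - {i}

    def test_shape_and_unknown_embedding(self, rng):
        ds = _ds(np.ones((6, 1)))
        ds.embeddings["e"] = rng.normal(size=(6, 3))
        g = knn_neighbors(ds, "e", k=2)
        assert g.indices.shape == (6, 2)
        with pytest.raises(KeyError, match="unknown embedding"):
            knn_neighbors(ds, "nope", k=2)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.normal(size=(200, 4))
        k = 7
        got = exact_knn(pts, k)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        expect = np.argsort(d, axis=1, kind="stable")[:, :k]
        np.testing.assert_array_equal(got, expect)

    def test_tie_break_prefers_lower_index(self):
        pts = np.array([[0.0], [1.0], [-1.0]])  # 1 and 2 equidistant from 0
        assert exact_knn(pts, 1)[0, 0] == 1
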