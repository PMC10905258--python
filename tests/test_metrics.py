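"""k-BET, LISI, silhouette, F1 combiners and the composite score."""

import numpy as np
import pytest
from scipy import stats as sps

from batcheval import (IntegratedDataset, NeighborGraph, batcheval_score,
                       evaluate_embedding, f1_lisi, f1_ss, inverse_simpson,
                       kbet, lisi_scores, silhouette_scores)
from batcheval.metrics import leiden_fallback_types


def _ring_graph(n, k):
    idx = np.array([[(i + d) % n for d in range(1, k + 1)] for i in range(n)])
    return NeighborGraph(indices=idx, k=k)


class TestKbet:
    def test_perfectly_mixed_neighborhood_accepted(self):
        # alternating labels on a ring: every 10-neighborhood holds 5/5
        n, k = 40, 10
        graph = _ring_graph(n, k)
        batch = np.array(["a", "b"] * (n // 2))
        res = kbet(graph, batch, seed=0)
        assert res.chi_mean == pytest.approx(0.0, abs=1e-12)
        assert res.accept_rate == 1.0 and res.p_summary == pytest.approx(1.0)

    def test_hand_chi_square_pure_neighborhood(self):
        # neighborhood counts [10, 0] with f=(0.5, 0.5), k=10:
        # kappa = 25/5 + 25/5 = 10, p = P(chi2_1 >= 10) ~ 0.00157 -> rejected
        n, k = 40, 10
        idx = np.array([[(i + 2 * d) % n for d in range(1, k + 1)]
                        for i in range(n)])  # same-parity neighbors only
        graph = NeighborGraph(indices=idx, k=k)
        batch = np.array(["a", "b"] * (n // 2))
        res = kbet(graph, batch, alpha=0.05, seed=0)
        assert res.chi_mean == pytest.approx(10.0, abs=1e-12)
        assert res.p_summary == pytest.approx(sps.chi2.sf(10, 1), abs=1e-10)
        assert res.accept_rate == 0.0

    def test_random_labels_mostly_accepted(self, rng):
        pts = rng.normal(size=(500, 5))
        from batcheval.preprocess import exact_knn

        graph = NeighborGraph(indices=exact_knn(pts, 25), k=25)
        batch = rng.choice(["a", "b"], size=500)
        res = kbet(graph, batch, alpha=0.05, seed=0)
        assert res.accept_rate >= 0.85

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.normal(size=(90, 3))
        from batcheval.preprocess import exact_knn

        k = 15
        graph = NeighborGraph(indices=exact_knn(pts, k), k=k)
        batch = rng.choice(["a", "b", "c"], size=90, p=[0.5, 0.3, 0.2])
        res = kbet(graph, batch, sample_fraction=1.0, min_sample=90, seed=0)
        names = sorted(set(batch))
        f = np.array([(batch == b).mean() for b in names])
        kappas = []
        for j in range(90):
            counts = np.array([(batch[graph.indices[j]] == b).sum() for b in names])
            kappas.append((((counts - f * k) ** 2) / (f * k)).sum())
        assert res.chi_mean == pytest.approx(np.mean(kappas), abs=1e-10)

    def test_small_k_warns(self):
        graph = _ring_graph(20, 4)
        with pytest.warns(UserWarning, match="chi-square"):
            kbet(graph, np.array(["a", "b"] * 10), seed=0)


class TestLisi:
    def test_pure_neighborhood_minimum(self):
        graph = _ring_graph(12, 3)
        labels = np.repeat("a", 12)
        np.testing.assert_allclose(inverse_simpson(graph, labels), 1.0)

    def test_half_half_neighborhood(self):
        # self + 3 neighbors, proportions (0.5, 0.5) -> inverse Simpson = 2
        idx = np.array([[1, 2, 3], [0, 2, 3], [3, 0, 1], [2, 0, 1]])
        graph = NeighborGraph(indices=idx, k=3)
        labels = np.array(["a", "a", "b", "b"])
        np.testing.assert_allclose(inverse_simpson(graph, labels), 2.0)

    def test_uniform_labels_reach_label_count(self):
        n, b = 30, 3
        graph = _ring_graph(n, b - 1)  # self + 2 neighbors, one of each label
        labels = np.array([f"l{i % b}" for i in range(n)])
        np.testing.assert_allclose(inverse_simpson(graph, labels), float(b))

    def test_single_level_label_set_zero(self):
        graph = _ring_graph(10, 3)
        with pytest.warns(UserWarning, match="single-level"):
            res = lisi_scores(graph, np.repeat("a", 10),
                              np.array(["t0", "t1"] * 5))
        assert res.iLISI == 0.0

    def test_minmax_normalization_bounds(self, rng):
        pts = rng.normal(size=(100, 3))
        from batcheval.preprocess import exact_knn

        graph = NeighborGraph(indices=exact_knn(pts, 10), k=10)
        res = lisi_scores(graph, rng.choice(["a", "b"], 100),
                          rng.choice(["t", "u", "v"], 100))
        assert 0.0 <= res.iLISI <= 1.0 and 0.0 <= res.cLISI <= 1.0


class TestF1Combiners:
    def test_lisi_f1_printed_value(self):
        assert round(f1_lisi(0.0154, 0.0386), 4) == 0.0303

    def test_lisi_f1_edges(self):
        assert f1_lisi(0.0, 0.5) == 0.0
        assert f1_lisi(1.0, 0.0) == pytest.approx(1.0)  # harmonic mean of (1,1)
        assert f1_lisi(0.0, 1.0) == 0.0  # zero denominator

    def test_ss_f1_table_consistent(self):
        assert round(f1_ss(0.6675, 0.6155), 4) == 0.4318
        assert f1_ss(0.7842, 0.4911) == pytest.approx(0.2999, abs=2e-4)

    def test_ss_f1_primed_mode(self):
        assert round(f1_ss(0.6675, 0.6155, mode="equation_9"), 4) == 0.2757

    def test_ss_f1_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            f1_ss(0.5, 0.5, mode="nope")

    def test_composite_is_exact_mean(self):
        s = batcheval_score(0.0303, 0.4318, 0.0194)
        assert s.batcheval == (0.0303 + 0.4318 + 0.0194) / 3
        assert batcheval_score(1.0, 1.0, 1.0).batcheval == 1.0

    def test_composite_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="accept_rate"):
            batcheval_score(0.5, 0.5, 1.2)


class TestSilhouette:
    def test_two_tight_far_clusters(self):
        emb = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array(["a", "a", "b", "b"])
        res = silhouette_scores(emb, labels, labels)
        assert res.iSS > 0.95 and res.cSS > 0.95

    def test_random_labels_near_zero(self, rng):
        emb = rng.normal(size=(200, 3))
        labels = rng.choice(["a", "b"], size=200)
        res = silhouette_scores(emb, labels, labels)
        assert abs(res.iSS) <= 0.1

    def test_bounds_and_subsampling(self, rng):
        emb = rng.normal(size=(300, 2))
        labels = rng.choice(["a", "b", "c"], size=300)
        res = silhouette_scores(emb, labels, labels, subsample=100, seed=1)
        assert -1.0 <= res.iSS <= 1.0

    def test_single_level_zero_with_warning(self, rng):
        emb = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning, match="single-level"):
            res = silhouette_scores(emb, np.repeat("a", 10),
                                    np.array(["t", "u"] * 5))
        assert res.iSS == 0.0


class TestEvaluateEmbedding:
    def test_bundle_components_in_range_and_mean(self, strong_effect_dataset):
        bundle = evaluate_embedding(strong_effect_dataset, "pca", seed=0)
        s = bundle.summary
        for v in (s.f1_lisi, s.f1_ss, s.accept_rate):
            assert 0.0 <= v <= 1.0
        assert s.batcheval == (s.f1_lisi + s.f1_ss + s.accept_rate) / 3
        # strong batch effect: classifier confident, kBET rejects
        assert bundle.classifier.domain_acc > 0.9
        assert bundle.kbet.accept_rate < 0.1

    def test_fallback_cluster_labels(self, strong_effect_dataset):
        ds = strong_effect_dataset.copy()
        ds.cell_type = None
        bundle = evaluate_embedding(ds, "pca", seed=0)
        assert bundle.types_source == "leiden_clusters"

    def test_leiden_fallback_is_seeded(self, rng):
        from batcheval.preprocess import exact_knn

        pts = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(8, 1, (50, 3))])
        graph = NeighborGraph(indices=exact_knn(pts, 10), k=10)
        l1 = leiden_fallback_types(graph, seed=0)
        l2 = leiden_fallback_types(graph, seed=0)
        np.testing.assert_array_equal(l1, l2)
        # the two blobs land in different clusters
        assert set(l1[:50]) & set(l1[50:]) == set()
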