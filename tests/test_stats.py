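"""Statistical test battery: ANOVA + F reference, Kruskal-Wallis, K-S,
contingency association."""

import numpy as np
import pytest
from scipy import stats as sps

from batcheval import (anova_total_counts, contingency_association,
                       f_critical, kruskal_wallis_h, ks_pairwise)
from batcheval.stats import quartile_condition, run_stat_battery


class TestAnova:
    def test_hand_anova(self):
        totals = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        batch = np.repeat(["a", "b", "c"], 3)
        res = anova_total_counts(totals, batch)
        assert res.F == pytest.approx(3.0, abs=1e-12)  # SSB/df1=3, SSW/df2=1
        assert res.n_batch == 3 and res.n_sample == 9

    def test_identical_groups_give_zero(self):
        totals = np.tile([1.0, 2.0, 3.0], 3)
        res = anova_total_counts(totals, np.repeat(["a", "b", "c"], 3))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError, match="two observations"):
            anova_total_counts(np.arange(4.0), np.array(["a", "a", "a", "b"]))

    def test_null_exceedance_rate_near_alpha(self, rng):
        # one homogeneous sample split at random into 3 groups: F should
        # exceed F_ref in about alpha of replicates
        n, reps, alpha = 120, 500, 0.05
        exceed = 0
        for _ in range(reps):
            totals = rng.normal(100, 10, size=n)
            batch = rng.permutation(np.repeat(["a", "b", "c"], n // 3))
            res = anova_total_counts(totals, batch, alpha=alpha)
            exceed += res.F > res.F_ref
        # binomial(500, 0.05): mean 25, sd ~4.9; accept within ~4 sd
        assert 6 <= exceed <= 45

    def test_permutation_invariance(self, rng):
        totals = rng.normal(size=30)
        batch = np.repeat(["a", "b", "c"], 10)
        perm = rng.permutation(30)
        r1 = anova_total_counts(totals, batch)
        r2 = anova_total_counts(totals[perm], batch[perm])
        assert r1.F == pytest.approx(r2.F, rel=1e-12)


class TestFCritical:
    def test_closed_form_for_df1_2(self):
        # for df1=2 the F quantile has the closed form d*(a^(-2/d)-1)/2
        for d in (10, 100, 1000):
            closed = d * (0.05 ** (-2.0 / d) - 1.0) / 2.0
            assert f_critical(2, d, 0.95) == pytest.approx(closed, abs=1e-10)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            f_critical(0, 5, 0.95)
        with pytest.raises(ValueError):
            f_critical(2, 5, 1.5)


class TestKruskalWallis:
    def test_symmetric_ties_give_zero(self):
        res = kruskal_wallis_h(np.array([1, 2, 3, 1, 2, 3], dtype=float),
                               np.repeat(["a", "b"], 3))
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_hand_rank_sums(self):
        res = kruskal_wallis_h(np.array([1, 2, 3, 4, 5, 6], dtype=float),
                               np.repeat(["a", "b"], 3))
        # R_a=6, R_b=15: H = 12/42*(36/3+225/3)-21 = 27/7
        assert res.H == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-12)
        assert res.rank_sums == {"a": 6.0, "b": 15.0}

    def test_all_identical_defined_zero(self):
        res = kruskal_wallis_h(np.ones(6), np.repeat(["a", "b"], 3))
        assert res.H == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(size=60), 1)  # rounding induces ties
        groups = rng.choice(["a", "b", "c"], size=60)
        res = kruskal_wallis_h(values, groups)
        ref = sps.kruskal(*[values[groups == g] for g in ("a", "b", "c")])
        assert res.H == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestKS:
    def test_identical_samples(self):
        r = ks_pairwise(np.tile([1.0, 2.0, 3.0], 2), np.repeat(["a", "b"], 3))
        assert r[0].stat == 0.0

    def test_disjoint_supports(self):
        r = ks_pairwise(np.array([1, 2, 3, 4, 5, 6], dtype=float),
                        np.repeat(["a", "b"], 3))
        assert r[0].stat == 1.0

    def test_hand_ecdf_gap(self):
        r = ks_pairwise(np.array([1.0, 2.0, 1.0, 3.0]),
                        np.array(["a", "a", "b", "b"]))
        assert r[0].stat == pytest.approx(0.5)
        assert r[0].n_sample == 4

    def test_symmetry_and_pair_count(self, rng):
        totals = rng.normal(size=30)
        batch = rng.choice(["a", "b", "c"], size=30)
        res = {r.pair: r.stat for r in ks_pairwise(totals, batch)}
        assert len(res) == 3
        flipped = np.where(batch == "a", "b", np.where(batch == "b", "a", "c"))
        res2 = {r.pair: r.stat for r in ks_pairwise(totals, flipped)}
        assert res[("a", "b")] == pytest.approx(res2[("a", "b")])


class TestAssociation:
    @staticmethod
    def _labels(table):
        cond, batch = [], []
        for i, row in enumerate(table):
            for j, count in enumerate(row):
                cond += [f"c{i}"] * count
                batch += [f"b{j}"] * count
        return np.array(cond), np.array(batch)

    def test_exact_independence(self):
        res = contingency_association(*self._labels([[10, 10], [10, 10]]))
        assert res.chi2 == 0.0 and res.cramers_v == 0.0

    def test_perfect_association(self):
        res = contingency_association(*self._labels([[10, 0], [0, 10]]))
        assert res.cramers_v == pytest.approx(1.0)

    def test_hand_chi_square(self):
        res = contingency_association(*self._labels([[30, 10], [10, 30]]))
        assert res.chi2 == pytest.approx(20.0)
        assert res.cramers_v == pytest.approx(0.5)
        assert res.pearson_c == pytest.approx(np.sqrt(20 / (20 + 80)))  # N=80

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="two levels"):
            contingency_association(np.array(["c"] * 4),
                                    np.array(["a", "a", "b", "b"]))


class TestBattery:
    def test_quartile_fallback_condition(self, rng):
        cond = quartile_condition(rng.normal(size=40))
        _, counts = np.unique(cond, return_counts=True)
        assert (counts == 10).all()

    def test_full_battery_on_simulated_data(self, strong_effect_dataset):
        # inject an unambiguous depth difference so the total-count tests
        # must fire: one batch sequenced twice as deep
        ds = strong_effect_dataset.copy()
        mask = np.asarray(ds.batch) == "batch0"
        ds.matrix[mask] *= 2.0
        bundle = run_stat_battery(ds)
        assert bundle.anova.F > bundle.anova.F_ref
        assert len(bundle.ks_pairs) == 3
        assert bundle.kruskal.p_value < 0.05
        assert bundle.condition_source == "cell_type"
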