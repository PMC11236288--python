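"""Statistical machinery: MWU against exhaustive enumeration, combiner
closed forms, BH step-up, calibration, and the full scoring pipeline."""

import itertools

import numpy as np
import pytest
from scipy import stats

from oracles import (bh_stepup, brute_force_auroc, chi2_sf_4df,
                     mwu_exact_p_greater)
from protogsea.enrichment import (bh_adjust, fisher_combine, mwu_test,
                                  pearson_combine, score_gene_sets)
from protogsea.network import SimilarityTensor
from protogsea.training import FoldResult


class TestMWU:
    def test_extreme_separation_exact_p(self):
        # a completely above b: U is maximal, p = 1 / C(5, 2) = 0.1
        assert mwu_test([3, 4, 5], [1, 2]) == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_large_p(self):
        assert mwu_test([1, 2, 3], [1, 2, 3]) >= 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])

    def test_exact_path_matches_enumeration_all_small_sizes(self):
        """Tie-free groups with n1+n2 <= 12 agree with brute-force
        enumeration of every rank assignment to 1e-12."""
        rng = np.random.default_rng(0)
        for n1, n2 in itertools.product(range(1, 7), range(1, 7)):
            if n1 + n2 > 12:
                continue
            vals = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
            a, b = vals[:n1], vals[n1:]
            assert mwu_test(a, b) == pytest.approx(
                mwu_exact_p_greater(a, b), abs=1e-12), (n1, n2)

    def test_u_statistic_equals_brute_force_auroc(self):
        """U/(n1 n2) is the auROC of the pooled scores against group
        labels, on 100 random instances."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(3, 15, size=2)
            a = rng.normal(0.5, 1.0, n1)
            b = rng.normal(0.0, 1.0, n2)
            u = stats.mannwhitneyu(a, b, alternative="greater").statistic
            auroc = brute_force_auroc(np.concatenate([a, b]),
                                      [1] * n1 + [0] * n2)
            assert u / (n1 * n2) == pytest.approx(auroc, abs=1e-12)

    def test_exact_and_normal_paths_agree_for_moderate_sizes(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0.3, 1.0, 11)
            b = rng.normal(0.0, 1.0, 10)
            exact = stats.mannwhitneyu(a, b, alternative="greater",
                                       method="exact").pvalue
            approx = stats.mannwhitneyu(a, b, alternative="greater",
                                        method="asymptotic",
                                        use_continuity=True).pvalue
            assert abs(exact - approx) < 0.02


class TestCombiners:
    def test_fisher_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_fisher_closed_form_two_halves(self):
        # statistic -2*2*ln(0.5) = 2.7726; chi^2_4 survival in closed form
        x = -2 * 2 * np.log(0.5)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(
            chi2_sf_4df(x), abs=1e-6)
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=2e-4)

    def test_fisher_zero_input_clamped(self):
        assert fisher_combine([0.0, 0.5]) < 1e-100

    def test_pearson_closed_form_two_halves(self):
        x = -2 * 2 * np.log(0.5)
        assert pearson_combine([0.5, 0.5]) == pytest.approx(
            1.0 - chi2_sf_4df(x), abs=1e-6)
        assert pearson_combine([0.5, 0.5]) == pytest.approx(0.4034, abs=2e-4)

    def test_pearson_limits(self):
        assert pearson_combine([1e-12, 1e-12]) < 1e-10
        assert pearson_combine([1.0 - 1e-12, 0.999999]) > 1.0 - 1e-6

    def test_pearson_sensitive_to_largest(self):
        # one large p keeps Pearson away from 0 while Fisher collapses
        ps = [1e-10, 0.6]
        assert pearson_combine(ps) > 0.1
        assert fisher_combine(ps) < 1e-6


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.02]), [0.02])

    def test_textbook_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], rtol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_independent_stepup_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ps = rng.random(rng.integers(2, 30))
            np.testing.assert_allclose(bh_adjust(ps), bh_stepup(ps),
                                       rtol=1e-10)

    def test_order_preserved_and_capped(self):
        ps = [0.9, 0.001, 0.5]
        q = bh_adjust(ps)
        assert q[1] < q[2] <= q[0] <= 1.0


class TestCalibration:
    def test_mwu_null_p_values_uniform(self):
        """Same-distribution groups: p-values pass a KS uniformity check
        over 1000 replicates at alpha=0.01."""
        rng = np.random.default_rng(7)
        ps = [mwu_test(rng.normal(size=30), rng.normal(size=30))
              for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_fisher_uniform_inputs_stay_uniform(self):
        rng = np.random.default_rng(8)
        ps = [fisher_combine(rng.random(3)) for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_pearson_uniform_inputs_stay_uniform(self):
        rng = np.random.default_rng(9)
        ps = [pearson_combine(rng.random(3)) for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bh_controls_empirical_fdr(self):
        """80 uniform nulls + 20 strong signals: mean false discovery
        proportion at q<0.05 stays near 0.05 * m0/m."""
        rng = np.random.default_rng(10)
        fdp = []
        for _ in range(400):
            ps = np.concatenate([rng.random(80),
                                 rng.beta(0.05, 1.0, size=20)])
            q = bh_adjust(ps)
            disc = q < 0.05
            if disc.any():
                fdp.append((disc[:80].sum()) / disc.sum())
            else:
                fdp.append(0.0)
        assert np.mean(fdp) <= 0.05 * 0.8 + 0.02


def _fake_fold(s, y, fold=0):
    n, T, C = s.shape
    sim = SimilarityTensor(s=s, posterior=s / s.sum(2, keepdims=True),
                           u=np.ones((n, T, 1)),
                           y_hat=np.full((n, C), 1.0 / C),
                           z=np.zeros((n, T, 2)))
    return FoldResult(fold=fold, net=None, sim=sim,
                      test_idx=np.arange(n), train_idx=np.arange(0),
                      y_test=y, q_test=None,
                      set_accuracy=np.zeros(T), history=[])


class TestScoreGeneSets:
    def test_single_fold_matches_chained_oracles(self):
        """Hand-constructed scores: combined p equals Fisher of the two
        directly computed MWU p-values; K=1 makes Pearson an identity on
        arrays of length one (same chi-squared df on the same value)."""
        y = np.array([1, 1, 1, 2, 2])
        s = np.zeros((5, 1, 2))
        s[:, 0, 0] = [5, 4, 3, 1, 2]     # class-1 cells outrank on k=1
        s[:, 0, 1] = [1, 2, 3, 5, 4]     # class-2 cells outrank on k=2
        table = score_gene_sets([_fake_fold(s, y)], ["set"], [7],
                                subsample_per_class=500, seed=0)
        p1 = mwu_exact_p_greater([5, 4, 3], [1, 2])
        p2 = mwu_exact_p_greater([5, 4], [1, 2, 3])
        fisher = fisher_combine([p1, p2])
        expected = pearson_combine([fisher])
        row = table.table.iloc[0]
        assert row["p_class1_fold0"] == pytest.approx(p1, abs=1e-12)
        assert row["p_class2_fold0"] == pytest.approx(p2, abs=1e-12)
        assert row["p_fold0"] == pytest.approx(fisher, rel=1e-9)
        assert row["combined_p"] == pytest.approx(expected, rel=1e-9)

    def test_large_subsample_cap_is_identity(self):
        rng = np.random.default_rng(4)
        y = np.repeat([1, 2], 20)
        s = rng.random((40, 2, 2))
        t_all = score_gene_sets([_fake_fold(s, y)], ["a", "b"], [3, 4],
                                subsample_per_class=1000, seed=1)
        t_cap = score_gene_sets([_fake_fold(s, y)], ["a", "b"], [3, 4],
                                subsample_per_class=40, seed=99)
        np.testing.assert_allclose(t_all.table["combined_p"],
                                   t_cap.table["combined_p"])

    def test_subsampling_is_seed_deterministic(self):
        rng = np.random.default_rng(5)
        y = np.repeat([1, 2], 50)
        s = rng.random((100, 1, 2))
        t1 = score_gene_sets([_fake_fold(s, y)], ["a"], [3],
                             subsample_per_class=20, seed=7)
        t2 = score_gene_sets([_fake_fold(s, y)], ["a"], [3],
                             subsample_per_class=20, seed=7)
        np.testing.assert_array_equal(t1.table["combined_p"],
                                      t2.table["combined_p"])

    def test_missing_class_in_fold_rejected(self):
        y = np.ones(10, int)
        s = np.random.default_rng(0).random((10, 1, 2))
        with pytest.raises(ValueError, match="class 2"):
            score_gene_sets([_fake_fold(s, y)], ["a"], [3])

    def test_rows_sorted_by_q(self):
        rng = np.random.default_rng(6)
        y = np.repeat([1, 2], 15)
        s = rng.random((30, 5, 2))
        s[y == 1, 2, 0] += 3.0   # make set index 2 enriched
        s[y == 2, 2, 1] += 3.0
        table = score_gene_sets([_fake_fold(s, y)],
                                [f"s{i}" for i in range(5)], [1] * 5,
                                seed=0).table
        assert table["q_value"].is_monotonic_increasing
        assert table.iloc[0]["set"] == "s2"

    def test_table_write_round_trip(self, tmp_path):
        import pandas as pd

        y = np.repeat([1, 2], 10)
        s = np.random.default_rng(1).random((20, 2, 2))
        table = score_gene_sets([_fake_fold(s, y)], ["a", "b"], [3, 4])
        table.write(tmp_path / "res.tsv", metadata={"K": 1})
        back = pd.read_csv(tmp_path / "res.tsv", sep="\t")
        assert list(back["set"]) == list(table.table["set"])
        assert (tmp_path / "res.tsv.meta.json").exists()
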