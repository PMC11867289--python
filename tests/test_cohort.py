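"""Paired cohort statistics on the packaged study tables."""

import itertools

import numpy as np
import pytest
from scipy import stats

import dscbezier as dz
from dscbezier.cohort import central_volume_mtt_factor, velocity_reduction_from_delay_prolongation


class TestCohortTable:
    def test_fixture_loads_eight_subjects(self, cohort_table):
        assert cohort_table.n == 8
        mtt_n, mtt_h = cohort_table.pair("mtt")
        assert mtt_n[0] == 2.98 and mtt_h[0] == 5.83

    def test_missing_column_rejected(self, cohort_table):
        with pytest.raises(ValueError, match="missing columns"):
            dz.CohortTable(cohort_table.data.drop(columns=["mtt_n_s"]))


class TestPairedT:
    def test_hand_computed_statistic(self):
        # textbook computation: d = y - x, t = mean(d) / (sd(d)/sqrt(n))
        x = np.array([10.0, 12.0, 9.0, 11.0, 10.5])
        y = x + np.array([1.0, 2.0, 0.5, 1.5, 1.0])
        d = y - x
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_hand = 2 * stats.t.sf(abs(t_hand), d.size - 1)
        t, p, df = dz.paired_t_test(x, y)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)
        assert df == 4

    def test_identical_samples_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            dz.paired_t_test(x, x)

    def test_mtt_columns_reproduce_printed_p(self, cohort_table):
        _, p, _ = dz.paired_t_test(*cohort_table.pair("mtt"))
        assert round(p, 4) == 0.0049

    def test_snr_columns_reproduce_printed_p(self, cohort_table):
        _, p, _ = dz.paired_t_test(*cohort_table.pair("snr"))
        assert round(p, 4) == 0.0055


class TestWilcoxonExact:
    def test_all_positive_differences_n8(self, cohort_table):
        # eight positive delay differences: two-sided p = 2/2^8
        w, p = dz.wilcoxon_signed_rank_exact(*cohort_table.pair("delta"))
        assert w == 36.0
        assert p == pytest.approx(2 / 256, abs=1e-12)

    def test_opposite_equal_ranks_n2(self):
        w, p = dz.wilcoxon_signed_rank_exact([0.0, 0.0], [1.0, -1.0])
        assert p == 1.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=8)
            d[d == 0] = 0.1
            x = np.zeros(8)
            w, p = dz.wilcoxon_signed_rank_exact(x, d)
            ranks = stats.rankdata(np.abs(d))
            ws = [
                sum(r for r, s in zip(ranks, signs) if s > 0)
                for signs in itertools.product([-1, 1], repeat=8)
            ]
            ws = np.asarray(ws)
            p_le = np.mean(ws <= w + 1e-12)
            p_ge = np.mean(ws >= w - 1e-12)
            p_brute = min(1.0, 2 * min(p_le, p_ge))
            assert p == pytest.approx(p_brute, abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = x + rng.normal(0.4, 1.0, size=10)
        _, p = dz.wilcoxon_signed_rank_exact(x, y)
        ref = stats.wilcoxon(y, x, method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            dz.wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])


class TestShapiroWilk:
    def test_normal_quantiles_high_w(self):
        x = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        w, _ = dz.shapiro_wilk(x)
        assert w > 0.99

    def test_delay_differences_non_normal(self, cohort_table):
        # consistent with the choice of a Wilcoxon test for the delays
        d_n, d_h = cohort_table.pair("delta")
        _, p = dz.shapiro_wilk(d_h - d_n)
        assert p < 0.05

    def test_outlier_lowers_w(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        w_clean, _ = dz.shapiro_wilk(x)
        w_dirty, _ = dz.shapiro_wilk(np.append(x[:-1], 15.0))
        assert w_dirty < w_clean

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dz.shapiro_wilk(np.full(8, 1.0))


class TestBonferroni:
    def test_study_pvalues_all_pass(self):
        flags = dz.bonferroni_gate([0.0049, 0.011, 0.0055, 0.0078], alpha=0.05, m=4)
        assert flags.all()

    def test_boundary_strict(self):
        assert not dz.bonferroni_gate([0.013], alpha=0.05, m=4)[0]
        assert not dz.bonferroni_gate([0.0125], alpha=0.05, m=4)[0]


class TestPearsonRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        rec = dz.pearson_with_regression(x, 2 * x + 1)
        assert rec["r"] == pytest.approx(1.0)
        assert rec["slope"] == pytest.approx(2.0)
        assert rec["intercept"] == pytest.approx(1.0)

    def test_etco2_aoef_association(self, cohort_table):
        et_n, _ = cohort_table.pair("etco2")
        aoef_n, _ = cohort_table.pair("aoef")
        rec = dz.pearson_with_regression(et_n, aoef_n)
        assert rec["r"] < 0  # higher CO2, lower extraction
        assert 0.82 <= abs(rec["r"]) <= 0.87
        assert rec["p"] < 0.0125

    def test_permutation_null_below_observed(self, cohort_table):
        et_n, _ = cohort_table.pair("etco2")
        aoef_n, _ = cohort_table.pair("aoef")
        r_obs = abs(dz.pearson_with_regression(et_n, aoef_n)["r"])
        rng = np.random.default_rng(2026)
        count = 0
        for _ in range(1000):
            r_perm = abs(stats.pearsonr(et_n, rng.permutation(aoef_n)).statistic)
            count += r_perm < r_obs
        assert count >= 950

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dz.pearson_with_regression(np.ones(5), np.arange(5.0))


class TestChangeSummaries:
    def test_mean_row_reproduced(self, cohort_table):
        s = dz.change_summaries(cohort_table)
        assert s.loc["mtt", "mean_n"] == pytest.approx(3.755, abs=5e-4)
        assert s.loc["mtt", "mean_h"] == pytest.approx(4.99125, abs=5e-4)
        assert s.loc["aoef", "mean_n"] == pytest.approx(22.5375, abs=5e-4)
        assert s.loc["aoef", "mean_h"] == pytest.approx(29.0, abs=5e-4)
        assert s.loc["snr", "mean_n"] == pytest.approx(34.4875, abs=5e-4)
        assert s.loc["snr", "mean_h"] == pytest.approx(24.175, abs=5e-4)
        assert s.loc["delta", "mean_n"] == pytest.approx(0.49325, abs=5e-5)
        assert s.loc["delta", "mean_h"] == pytest.approx(0.805875, abs=5e-5)

    def test_percent_changes(self, cohort_table):
        s = dz.change_summaries(cohort_table)
        assert round(s.loc["mtt", "mean_subject_ratio_pct"]) == 33
        assert round(s.loc["aoef", "mean_subject_ratio_pct"]) == 30
        assert round(s.loc["snr", "mean_subject_ratio_pct"]) == -28
        assert round(s.loc["delta", "ratio_of_means_pct"]) == 63

    def test_row_permutation_invariant(self, cohort_table, rng):
        shuffled = dz.CohortTable(cohort_table.data.sample(frac=1, random_state=4).reset_index(drop=True))
        s1 = dz.change_summaries(cohort_table)
        s2 = dz.change_summaries(shuffled)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), rtol=1e-12)


class TestDerivedFactors:
    def test_central_volume_factor(self):
        assert central_volume_mtt_factor(0.928, 0.693) == pytest.approx(1.339, abs=5e-4)

    def test_velocity_reduction(self):
        assert velocity_reduction_from_delay_prolongation(1.63) == pytest.approx(0.3865, abs=1e-3)


class TestPairedCohortModel:
    def test_fit_and_summary(self):
        res = dz.PairedCohort().fit()
        assert res.tests["significant"].all()
        assert res.tests.loc["delta", "test"] == "wilcoxon_exact"
        text = res.summary()
        assert "Bonferroni" in text and "hyperventilation" in text

    def test_reports_written(self, tmp_path):
        res = dz.PairedCohort().fit()
        res.to_csv(tmp_path)
        assert (tmp_path / "tests.csv").exists()
        assert (tmp_path / "change_summaries.csv").exists()
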