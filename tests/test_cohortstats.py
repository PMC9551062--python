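import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from watchwalk import cohortstats as cs
from watchwalk.simulate import simulate_cohort


class TestICC:
    def test_identical_columns_give_unity(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 7))
        assert cs.icc_2k(m).icc == pytest.approx(1.0)

    def test_variance_components_model_matches_closed_form(self):
        # subject variance 9, residual 1, no day effect, k=7:
        # ICC(2,k) = 9 / (9 + 1/7) = 0.9846
        df, _, truth = simulate_cohort(
            500, {"all": {}}, n_days=7, master_seed=3,
            base_means={"x": 10.0}, between_sd={"x": 3.0}, within_sd={"x": 1.0},
        )
        m = df.pivot(index="subject_id", columns="day_index", values="x").to_numpy()
        res = cs.icc_2k(m)
        assert res.icc == pytest.approx(9 / (9 + 1 / 7), abs=0.01)
        assert res.var_subject == pytest.approx(9.0, rel=0.2)
        assert res.var_residual == pytest.approx(1.0, rel=0.2)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((200, 7))
        assert abs(cs.icc_2k(m).icc) < 0.05

    def test_matches_pingouin_on_balanced_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        m = rng.standard_normal((12, 4)) + rng.standard_normal((12, 1)) * 2
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "day": np.tile(np.arange(4), 12),
            "y": m.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject", raters="day",
                                       ratings="y")
        # two-way random, absolute agreement, average of k raters
        is_a_k = ref["Type"].isin(["ICC2k", "ICC(A,k)"])
        ref_icc2k = float(ref.loc[is_a_k, "ICC"].iloc[0])
        assert cs.icc_2k(m).icc == pytest.approx(ref_icc2k, abs=1e-9)

    def test_shrout_fleiss_hand_fixture(self):
        # 5 subjects x 3 days; independent mean-squares computation below
        m = np.array([
            [7.0, 6.5, 7.2],
            [3.1, 3.6, 3.0],
            [5.0, 4.8, 5.5],
            [1.2, 1.0, 1.1],
            [9.4, 9.0, 9.8],
        ])
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((m - m.mean(1, keepdims=True) - m.mean(0) + grand) ** 2).sum()
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (msc - mse) / n)
        assert cs.icc_2k(m).icc == pytest.approx(expected, abs=1e-12)

    def test_excess_missingness_rejected(self):
        m = np.full((10, 5), np.nan)
        m[:, :3] = 1.0
        with pytest.raises(ValueError):
            cs.icc_2k(m)


class TestKruskalDunn:
    def test_separated_groups_all_pairwise_significant(self):
        rng = np.random.default_rng(6)
        v = np.concatenate([rng.normal(mu, 0.5, 40) for mu in (0, 5, 10)])
        g = np.repeat(["a", "b", "c"], 40)
        res = cs.kruskal_dunn(v, g)
        assert res.p < 1e-3
        assert (res.pairwise["p_adj"] < 1e-3).all()
        assert len(res.pairwise) == 3

    def test_two_groups_match_rank_sum_ordering(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)])
        g = np.repeat(["a", "b"], 30)
        res = cs.kruskal_dunn(v, g)
        u_p = sp_stats.mannwhitneyu(v[:30], v[30:]).pvalue
        assert res.p == pytest.approx(u_p, abs=0.02)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            cs.kruskal_dunn([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(300):
            v = rng.standard_normal(90)
            ps.append(cs.kruskal_dunn(v, np.repeat(["a", "b", "c"], 30),
                                      pairwise=False).p)
        assert sp_stats.ks_1samp(ps, sp_stats.uniform.cdf).pvalue > 0.01


class TestAnovaTukey:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(9)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                            rng.normal(5, 1, 30)])
        g = np.repeat(["a", "b", "c"], 30)
        res = cs.anova_tukey(v, g)
        assert res.p < 1e-6
        sig = res.pairwise[res.pairwise["p_adj"] < 0.01]
        assert set(map(tuple, sig[["group1", "group2"]].values)) == {
            ("a", "c"), ("b", "c")}

    def test_null_f_statistic_near_one_on_average(self):
        rng = np.random.default_rng(10)
        fs = [cs.anova_tukey(rng.standard_normal(60),
                             np.repeat(["a", "b", "c"], 20),
                             pairwise=False).statistic
              for _ in range(300)]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cs.anova_tukey([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestChiSquare:
    def test_independent_table_scores_zero(self):
        res = cs.chi_square_table([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_association(self):
        res = cs.chi_square_table([[50, 10], [10, 50]])
        assert res.statistic == pytest.approx(53.33, abs=0.01)
        assert res.df == 1

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            cs.chi_square_table([[5, 0], [3, 0]])


class TestMape:
    def test_exact_estimates_score_zero(self):
        assert cs.mape([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_uniform_five_percent_overestimate(self):
        truth = np.array([0.5, 1.0, 2.0])
        assert cs.mape(1.05 * truth, truth) == pytest.approx(5.0)

    def test_hand_computed_mixed_errors(self):
        assert cs.mape([1.1, 0.9], [1.0, 1.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(0.5, 2.0, 50)
        est = truth * rng.uniform(0.9, 1.1, 50)
        assert cs.mape(est, truth) == pytest.approx(cs.mape(3 * est, 3 * truth))

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            cs.mape([1.0], [0.0])
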