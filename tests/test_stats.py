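"""Statistical battery: summary reconstruction, exact tests, mixed model."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from titiduet.stats import (GroupSummary, anova_from_summary,
                            assumption_checks, bonferroni, kruskal_wallis,
                            lmm_random_intercept, manova_tests, outlier_flags,
                            pearson_correlation, signed_rank_null_pmf,
                            t_from_summary, wilcoxon_rank_sum,
                            wilcoxon_signed_rank_exact)


def sample_with_moments(mean, sd, n, seed=0):
    """A sample with exactly the requested mean and (ddof=1) SD."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestAnovaFromSummary:
    def test_equals_raw_anova_on_matched_data(self):
        summaries = [GroupSummary(10.0, 0.8, 7), GroupSummary(12.5, 0.5, 9),
                     GroupSummary(9.1, 1.1, 5)]
        samples = [sample_with_moments(s.mean, s.sd, s.n, seed=i)
                   for i, s in enumerate(summaries)]
        res = anova_from_summary(summaries)
        f_raw, p_raw = sps.f_oneway(*samples)
        assert res.value == pytest.approx(f_raw, rel=1e-10)
        assert res.p == pytest.approx(p_raw, rel=1e-8)

    def test_identical_means_give_zero(self):
        res = anova_from_summary([GroupSummary(5.0, 0.3, 6)] * 3)
        assert res.value == 0.0

    def test_f_equals_t_squared_for_two_groups(self):
        a, b = GroupSummary(10.0, 0.8, 7), GroupSummary(12.5, 0.5, 9)
        f = anova_from_summary([a, b])
        t = t_from_summary(a, b, "pooled")
        assert f.value == pytest.approx(t.value**2, rel=1e-12)
        assert f.p == pytest.approx(t.p, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([GroupSummary(1, 0.1, 1), GroupSummary(2, 0.1, 5)])


class TestTFromSummary:
    @pytest.mark.parametrize("kind,equal_var", [("pooled", True),
                                                ("welch", False)])
    def test_matches_scipy_on_matched_data(self, kind, equal_var):
        a, b = GroupSummary(3.2, 0.21, 8), GroupSummary(2.5, 0.4, 12)
        xa = sample_with_moments(a.mean, a.sd, a.n, seed=1)
        xb = sample_with_moments(b.mean, b.sd, b.n, seed=2)
        res = t_from_summary(a, b, kind)
        t_ref, p_ref = sps.ttest_ind(xa, xb, equal_var=equal_var)
        assert res.value == pytest.approx(t_ref, rel=1e-10)
        assert res.p == pytest.approx(p_ref, rel=1e-8)

    def test_identical_groups_give_zero(self):
        g = GroupSummary(4.0, 0.2, 10)
        assert t_from_summary(g, g).value == 0.0

    def test_zero_variance_unequal_means_is_infinite(self):
        res = t_from_summary(GroupSummary(1.0, 0.0, 5), GroupSummary(2.0, 0.0, 5))
        assert np.isinf(res.value)
        assert res.p == 0.0


class TestSignedRankExact:
    def test_all_negative_eight_pairs(self):
        res = wilcoxon_signed_rank_exact(v=0, n=8)
        assert res.p == 2 / 256  # 0.0078125

    def test_all_negative_seven_pairs(self):
        res = wilcoxon_signed_rank_exact(v=0, n=7)
        assert res.p == 2 / 128  # 0.015625

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_convolution_equals_sign_enumeration(self, n):
        ranks = np.arange(1, n + 1)
        support, pmf = signed_rank_null_pmf(ranks)
        counts = np.zeros(int(support[-1] * 2) + 1)
        for signs in itertools.product([0, 1], repeat=n):
            v = int(np.dot(signs, ranks))
            counts[2 * v] += 1
        assert np.allclose(pmf, counts / counts.sum())

    def test_matches_scipy_exact_on_differences(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal(12) + 0.6
        res = wilcoxon_signed_rank_exact(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(2, 15), st.integers(0, 120))
    def test_null_symmetry(self, n, v):
        total = n * (n + 1) // 2
        v = v % (total + 1)
        a = wilcoxon_signed_rank_exact(v=v, n=n).p
        b = wilcoxon_signed_rank_exact(v=total - v, n=n).p
        assert a == pytest.approx(b)

    def test_zeros_dropped_all_zero_rejected(self, caplog):
        with caplog.at_level("WARNING"):
            res = wilcoxon_signed_rank_exact([0.0, 1.0, 2.0, 3.0])
        assert "zero difference" in caplog.text
        assert res.df == 3
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_exact([0.0, 0.0])

    def test_large_n_uses_normal_approximation(self):
        d = np.linspace(0.5, 3.0, 30)
        res = wilcoxon_signed_rank_exact(d)
        assert "approximation" in res.method
        assert res.p < 0.001


class TestRankSum:
    def test_complete_separation_gives_zero_w(self):
        x = [1, 2, 3, 4, 5, 6]
        y = list(range(10, 25))
        res = wilcoxon_rank_sum(x, y)
        assert res.value == 0.0
        assert res.p < 0.001

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(5)
        y = rng.standard_normal(6) + 0.8
        res = wilcoxon_rank_sum(x, y)
        combined = np.concatenate([x, y])
        ranks = sps.rankdata(combined)
        n1 = len(x)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = [sum(c) - n1 * (n1 + 1) / 2
              for c in itertools.combinations(ranks, n1)]
        us = np.array(us)
        p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert res.p == pytest.approx(p_enum, rel=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(7)
        y = rng.standard_normal(9) + 0.5
        res = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.value == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_tied_pair_gives_p_one(self):
        res = wilcoxon_rank_sum([3.0], [3.0])
        assert res.p == 1.0


class TestKruskalWallis:
    def test_identical_groups_zero_statistic(self):
        g = [1.0, 1.0, 1.0]
        res = kruskal_wallis([g, g, g])
        assert res.value == 0.0
        assert res.p == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        groups = [np.round(rng.standard_normal(8), 1),
                  np.round(rng.standard_normal(6) + 0.5, 1),
                  np.round(rng.standard_normal(7) - 0.3, 1)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.value == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        groups = [rng.uniform(1, 2, 6), rng.uniform(1.5, 2.5, 8)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.value == pytest.approx(b.value)


class TestAssumptionsAndOutliers:
    def test_levene_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.standard_normal(10), rng.standard_normal(10)]
            f, p = sps.levene(*groups, center="mean")
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.03 < rate < 0.08  # binomial 3-sigma band around 5%

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            assumption_checks([[2.0, 2.0, 2.0, 2.0]])

    def test_shapiro_and_levene_reported(self):
        rng = np.random.default_rng(10)
        groups = [rng.standard_normal(12), rng.standard_normal(10)]
        results = assumption_checks(groups)
        assert [r.statistic for r in results] == ["W", "W", "F"]

    def test_single_extreme_point_flagged(self):
        x = np.concatenate([np.linspace(-1, 1, 20), [15.0]])
        flags = outlier_flags(x)
        assert flags.sum() == 1
        assert flags[-1]


class TestBonferroni:
    def test_basic_values(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0
        assert np.allclose(bonferroni([0.2, 0.04], 1), [0.2, 0.04])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_adjusted_dominates_raw(self, ps):
        adj = bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)


class TestMixedModel:
    def test_degenerate_single_measurement_reduces_to_ols(self):
        rng = np.random.default_rng(11)
        species = np.repeat(["a", "b", "c"], 8)
        duets = np.arange(24)  # one measurement per duet
        y = rng.standard_normal(24) + np.repeat([0.0, 1.0, 2.0], 8)
        fit = lmm_random_intercept(y, duets, species)
        assert fit.sigma_b2 <= 1e-6 * fit.sigma_e2
        X = np.column_stack([np.ones(24), species == "b", species == "c"])
        beta_ols = np.linalg.lstsq(X.astype(float), y, rcond=None)[0]
        assert np.allclose(list(fit.fixed_effects.values()), beta_ols, atol=1e-6)

    def test_recovers_intercept_sd(self):
        """Random-intercept SD recovered within 25% at the study scale."""
        rng = np.random.default_rng(12)
        sd_b, sd_e = 1.56, 1.2
        species = np.repeat([f"s{i}" for i in range(4)], 8)  # 32 duets
        estimates = []
        for _ in range(30):
            intercepts = rng.normal(0, sd_b, 32)
            rows_y, rows_d, rows_s = [], [], []
            for d in range(32):
                y = (intercepts[d] + 2.0 * (species[d] == "s1")
                     + rng.normal(0, sd_e, 12))
                rows_y.extend(y)
                rows_d.extend([d] * 12)
                rows_s.extend([species[d]] * 12)
            fit = lmm_random_intercept(rows_y, rows_d, rows_s)
            estimates.append(fit.sigma_b)
        assert np.mean(estimates) == pytest.approx(sd_b, rel=0.25)

    def test_matches_statsmodels_reference(self):
        import statsmodels.formula.api as smf
        import pandas as pd
        rng = np.random.default_rng(13)
        records = []
        for d in range(10):
            sp = "a" if d < 5 else "b"
            b = rng.normal(0, 1.0)
            for _ in range(6):
                records.append({"duet": d, "species": sp,
                                "y": b + (sp == "b") * 1.5 + rng.normal()})
        df = pd.DataFrame(records)
        fit = lmm_random_intercept(df.y, df.duet, df.species)
        ref = smf.mixedlm("y ~ species", df, groups=df.duet).fit(reml=True)
        assert fit.fixed_effects["species[b]"] == pytest.approx(
            ref.params["species[T.b]"], abs=1e-3)
        assert fit.sigma_b2 == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                             rel=0.02)
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=0.02)
        # Wald chi2 for the single fixed-effect contrast = (beta/se)^2
        se_ref = ref.bse["species[T.b]"]
        assert fit.wald_chi2 == pytest.approx(
            (ref.params["species[T.b]"] / se_ref) ** 2, rel=0.02)


class TestManova:
    def test_null_case_pillai_near_zero(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((400, 3))
        groups = np.repeat(["a", "b"], 200)
        res = {r.statistic: r for r in manova_tests(X, groups)}
        assert res["Pillai"].value < 0.05
        assert res["Pillai"].p > 0.01

    def test_two_group_pillai_equals_one_minus_wilks(self):
        rng = np.random.default_rng(15)
        X = np.vstack([rng.standard_normal((12, 3)),
                       rng.standard_normal((10, 3)) + 1.0])
        groups = np.array(["a"] * 12 + ["b"] * 10)
        res = {r.statistic: r for r in manova_tests(X, groups)}
        assert res["Pillai"].value == pytest.approx(1 - res["Lambda"].value)

    def test_matches_statsmodels_reference(self):
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(16)
        X = np.vstack([rng.standard_normal((10, 3)),
                       rng.standard_normal((12, 3)) + 0.8,
                       rng.standard_normal((9, 3)) - 0.5])
        groups = np.array(["a"] * 10 + ["b"] * 12 + ["c"] * 9)
        res = {r.statistic: r for r in manova_tests(X, groups)}
        dummies = np.column_stack([groups == "b", groups == "c"]).astype(float)
        exog = np.column_stack([np.ones(len(X)), dummies])
        ref = MANOVA(endog=X, exog=exog).mv_test(
            hypotheses=[("grp", np.array([[0, 1, 0], [0, 0, 1]]), None)])
        table = ref.results["grp"]["stat"]
        assert res["Lambda"].value == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), rel=1e-8)
        assert res["Pillai"].value == pytest.approx(
            float(table.loc["Pillai's trace", "Value"]), rel=1e-8)
        assert res["Pillai"].p == pytest.approx(
            float(table.loc["Pillai's trace", "Pr > F"]), rel=1e-6)

    def test_singular_scatter_rejected(self):
        X = np.zeros((12, 3))
        X[:, 0] = np.arange(12)
        X[:, 1] = 2 * X[:, 0]
        X[:, 2] = np.random.default_rng(0).standard_normal(12)
        with pytest.raises(ValueError, match="singular"):
            manova_tests(X, np.repeat(["a", "b"], 6))


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, x)
        assert res.value == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_published_scale_t_from_r(self):
        # construct n=36 data whose sample correlation is exactly 0.71
        rng = np.random.default_rng(17)
        x = rng.standard_normal(36)
        z = rng.standard_normal(36)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)
        z /= z.std()
        y = 0.71 * x + np.sqrt(1 - 0.71**2) * z
        res = pearson_correlation(x, y)
        assert res.value == pytest.approx(0.71, abs=1e-10)
        assert res.df == 34
        t = res.value * np.sqrt(res.df / (1 - res.value**2))
        assert t == pytest.approx(5.85, rel=0.01)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(18)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        res = pearson_correlation(x, y)
        r_direct = (np.cov(x, y, ddof=1)[0, 1]
                    / (x.std(ddof=1) * y.std(ddof=1)))
        assert res.value == pytest.approx(r_direct, rel=1e-12)
        ref = sps.pearsonr(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))
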