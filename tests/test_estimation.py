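"""Per-replicate estimation: transforms, OLS, mixed fits, rank tests, LRT."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import multilab as ml
from multilab.config import OutcomeSpec, SimulationConfig

from conftest import two_group_table
from _oracles import gaussian_lrt_rss, rank_sum_enumeration

GAUSS = OutcomeSpec("o", "gaussian")


class TestTransforms:
    @pytest.mark.parametrize("value,transform,expected", [
        (0.0, "log1p", 0.0),
        (600.0, "log1p", 6.398595),       # the immobility assay ceiling
        (144.0, "sqrt", 12.0),            # the arena's maximum distance
        (5.0, "none", 5.0),
    ])
    def test_known_values(self, value, transform, expected):
        assert ml.transform_response([value], transform)[0] == pytest.approx(expected, abs=1e-6)

    def test_negative_input_names_offending_index(self):
        with pytest.raises(ValueError, match="index 2"):
            ml.transform_response([1.0, 0.0, -3.0], "sqrt")


class TestGaussianFit:
    def test_identical_groups_give_zero_contrast(self):
        r = ml.fit_gaussian_model(two_group_table([1, 2, 3], [1, 2, 3]), GAUSS)
        assert r.estimate == pytest.approx(0.0)

    def test_shifted_groups_closed_form(self):
        # hand OLS: contrast 1, pooled s2 = 1, se = sqrt(2/3); p from the
        # t CDF oracle on 4 residual df
        r = ml.fit_gaussian_model(two_group_table([1, 2, 3], [2, 3, 4]), GAUSS)
        assert r.estimate == pytest.approx(1.0)
        assert r.se == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-4)
        p_oracle = 2 * stats.t.sf(1.0 / np.sqrt(2.0 / 3.0), df=4)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert r.inference == "t_residual_df"

    def test_contrast_invariant_to_constant_shift(self):
        a = ml.fit_gaussian_model(two_group_table([1, 2, 3], [4, 5, 7]), GAUSS)
        b = ml.fit_gaussian_model(two_group_table([11, 12, 13], [14, 15, 17]), GAUSS)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.se == pytest.approx(b.se)

    def test_flipping_reference_negates_contrast_and_swaps_ci(self):
        t = two_group_table([1, 2, 3], [2, 4, 5])
        a = ml.fit_gaussian_model(t, GAUSS)
        b = ml.fit_gaussian_model(t, OutcomeSpec("o", "gaussian",
                                                 treatment_reference="treated"))
        assert b.estimate == pytest.approx(-a.estimate)
        assert b.ci_low == pytest.approx(-a.ci_high)
        assert b.ci_high == pytest.approx(-a.ci_low)
        assert b.p_value == pytest.approx(a.p_value)

    def test_zero_residual_variance_flagged_degenerate(self):
        r = ml.fit_gaussian_model(two_group_table([2, 2, 2], [5, 5, 5]), GAUSS)
        assert r.estimate == pytest.approx(3.0)
        assert r.inference == "degenerate" and np.isnan(r.p_value)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="2 units"):
            ml.fit_gaussian_model(two_group_table([1], [2, 3]), GAUSS)

    def test_multi_lab_table_rejected(self):
        t = pd.concat([two_group_table([1, 2], [3, 4], lab_id="A"),
                       two_group_table([1, 2], [3, 4], lab_id="B")])
        with pytest.raises(ValueError, match="single laboratory"):
            ml.fit_gaussian_model(t, GAUSS)


class TestMixedFits:
    def test_logistic_zero_variance_equals_glm_route(self):
        cfg = ml.default_scenario("binary_repeated_choice", seed=8)
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "n_labs": 1,
                                          "units_per_group_per_lab": 15})
        tab = ml.simulate(cfg)
        spec = ml.spec_for_scenario(cfg)
        r0 = ml.fit_logistic_mixed_model(tab, spec, unit_sd=0.0)
        # independent route: statsmodels GLM on the scorable rows
        import statsmodels.api as sm
        sub = tab[tab.scorable]
        x = (sub.treatment != "brown").astype(float).to_numpy()
        glm = sm.GLM(sub.response.to_numpy(), np.column_stack([np.ones_like(x), x]),
                     family=sm.families.Binomial()).fit()
        assert r0.estimate == pytest.approx(glm.params[1], abs=1e-6)
        assert r0.se == pytest.approx(glm.bse[1], abs=1e-6)

    def test_proportion_zero_variances_equal_glm_route(self):
        cfg = ml.default_scenario("dish_proportion", seed=8)
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "n_labs": 1,
                                          "units_per_group_per_lab": 12})
        tab = ml.simulate(cfg)
        spec = ml.spec_for_scenario(cfg)
        r0 = ml.fit_proportion_mixed_model(tab, spec, unit_sd=0.0, olre_sd=0.0)
        import statsmodels.api as sm
        sub = tab[tab.trials >= 1]
        x = (sub.treatment != "larvae").astype(float).to_numpy()
        glm = sm.GLM(np.column_stack([sub.successes, sub.trials - sub.successes]),
                     np.column_stack([np.ones_like(x), x]),
                     family=sm.families.Binomial()).fit()
        assert r0.estimate == pytest.approx(glm.params[1], abs=1e-6)

    def test_wald_interval_brackets_estimate(self):
        cfg = ml.default_scenario("binary_repeated_choice", seed=4)
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "n_labs": 1})
        r = ml.fit_logistic_mixed_model(ml.simulate(cfg), ml.spec_for_scenario(cfg))
        assert r.ci_low < r.estimate < r.ci_high
        assert r.inference == "wald_z"
        assert "unit_intercept" in r.variance_components


class TestOverdispersion:
    def test_saturated_toy_has_zero_ratio(self):
        # every row is 1 of 2 at a fitted probability of exactly one half
        X = np.ones((8, 1))
        fit = ml.fit_binomial_glmm(X, np.full(8, 1.0), np.full(8, 2.0))
        t = ml.overdispersion_ratio(fit, np.full(8, 1.0), np.full(8, 2.0))
        assert t.value == pytest.approx(0.0, abs=1e-12)
        assert t.statistic_name == "dispersion_ratio"

    def test_correctly_specified_binomial_ratio_near_one(self):
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(200):
            m = np.full(60, 3.0)
            x = np.repeat([0.0, 1.0], 30)
            X = np.column_stack([np.ones(60), x])
            s = rng.binomial(3, 0.45 + 0.1 * x).astype(float)
            fit = ml.fit_binomial_glmm(X, s, m)
            ratios.append(ml.overdispersion_ratio(fit, s, m).value)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_omitted_olre_inflates_ratio(self):
        ratios = []
        for seed in range(40):
            cfg = ml.default_scenario("dish_proportion", seed=seed)
            cfg = SimulationConfig.from_dict({**cfg.to_dict(), "n_labs": 1,
                                              "units_per_group_per_lab": 30,
                                              "unit_re_sd": 0.0, "olre_sd": 1.0})
            tab = ml.simulate(cfg)
            sub = tab[tab.trials >= 1]
            x = (sub.treatment != "larvae").astype(float).to_numpy()
            X = np.column_stack([np.ones_like(x), x])
            s, m = sub.successes.to_numpy(float), sub.trials.to_numpy(float)
            fit = ml.fit_binomial_glmm(X, s, m)       # no OLRE in the fit
            ratios.append(ml.overdispersion_ratio(fit, s, m).value)
        assert np.mean(ratios) > 1.2

    def test_nonpositive_df_rejected(self):
        X = np.ones((1, 1))
        fit = ml.fit_binomial_glmm(X, [1.0], [2.0])
        with pytest.raises(ValueError, match="degrees of freedom"):
            ml.overdispersion_ratio(fit, [1.0], [2.0])


class TestRankSum:
    @pytest.mark.parametrize("a,b,w", [
        ((3, 4), (1, 2), 4.0),
        ((1, 2), (3, 4), 0.0),
        ((1, 3, 5), (2, 4, 6), 3.0),
    ])
    def test_w_statistic(self, a, b, w):
        assert ml.rank_sum_test(a, b).value == w

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.permutation(20)[:4].astype(float)
            b = rng.permutation(np.arange(20, 40))[:5].astype(float)
            w_o, p_o = rank_sum_enumeration(a, b)
            t = ml.rank_sum_test(a, b)
            assert t.value == pytest.approx(w_o)
            assert t.p_value == pytest.approx(p_o, abs=1e-12)

    def test_small_tie_free_example_exact_p(self):
        # frozen from the enumeration oracle over all 20 assignments
        t = ml.rank_sum_test((1, 3, 5), (2, 4, 6))
        assert t.p_value == pytest.approx(0.7)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        t = ml.rank_sum_test(a, b)
        assert 0 <= t.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ml.rank_sum_test([], [1.0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert ml.spearman_correlation([1, 2, 3], [3, 2, 1]).value == pytest.approx(-1.0)
        assert ml.spearman_correlation([1, 2, 3], [1, 2, 3]).value == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ml.spearman_correlation([1, 1, 1], [1, 2, 3])


class TestInteractionLRT:
    def test_duplicated_lab_gives_zero_statistic(self):
        t1 = two_group_table([1, 2, 3, 4], [3, 4, 5, 7], lab_id="A")
        t2 = t1.assign(lab_id="B", unit_id=t1.unit_id + "_b")
        t = pd.concat([t1, t2], ignore_index=True)
        res = ml.interaction_lrt(t, GAUSS)
        assert res.value == pytest.approx(0.0, abs=1e-6)
        assert res.df == 1

    def test_matches_closed_form_rss_oracle(self):
        cfg = ml.default_scenario("gaussian_two_group", seed=13)
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "lab_slope_sd": 0.8})
        tab = ml.simulate(cfg)
        spec = ml.spec_for_scenario(cfg)
        res = ml.interaction_lrt(tab, spec)
        y = np.log1p(tab.response.to_numpy())
        x = (tab.treatment != "control").astype(float).to_numpy()
        chi2_o = gaussian_lrt_rss(y, x, tab.lab_id.to_numpy())
        assert res.value == pytest.approx(chi2_o, rel=1e-9)
        assert res.df == 2

    def test_binary_family_detects_injected_heterogeneity(self):
        cfg = ml.default_scenario("binary_repeated_choice", seed=3)
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "lab_slope_sd": 1.5})
        tab = ml.simulate(cfg)
        res = ml.interaction_lrt(tab, ml.spec_for_scenario(cfg))
        assert res.statistic_name == "chi2" and res.df == 2
        assert res.p_value < 0.05

    def test_single_treatment_lab_names_offender(self):
        t1 = two_group_table([1, 2, 3], [4, 5, 6], lab_id="A")
        t2 = two_group_table([1, 2, 3], [], lab_id="B")
        t = pd.concat([t1, t2], ignore_index=True)
        with pytest.raises(ValueError, match="'B'"):
            ml.interaction_lrt(t, GAUSS)
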