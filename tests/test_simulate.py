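"""Generator structure: determinism, counts, moments, thinning, heterogeneity."""
import numpy as np
import pandas as pd
import pytest

import multilab as ml
from multilab.config import SimulationConfig


def cfg(**kw):
    base = dict(archetype="gaussian_two_group", n_labs=3, units_per_group_per_lab=30,
                seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_identical_config_and_seed_give_identical_tables(self):
        for arch in ("gaussian_two_group", "binary_repeated_choice", "dish_proportion"):
            c = ml.default_scenario(arch, seed=11)
            a = ml.simulate(c).to_csv(index=False)
            b = ml.simulate(ml.SimulationConfig.from_dict(c.to_dict())).to_csv(index=False)
            assert a == b, arch

    def test_different_seed_changes_data(self):
        a = ml.simulate(cfg(seed=1))
        b = ml.simulate(cfg(seed=2))
        assert not a["response"].equals(b["response"])

    def test_adding_a_lab_preserves_existing_labs(self):
        a = ml.simulate(cfg(n_labs=3, seed=5))
        b = ml.simulate(cfg(n_labs=4, seed=5))
        three = b[b.lab_id.isin(a.lab_id.unique())].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, three)


class TestGaussianArchetype:
    def test_row_counts_match_study_design(self):
        # 3 labs x 30 per group x 2 groups = 180 individuals
        t = ml.simulate(cfg())
        assert len(t) == 180
        assert (t.groupby("lab_id").size() == 60).all()

    def test_degenerate_noise_pins_group_means_at_lab_intercepts(self):
        c = cfg(alpha=2.0, beta=0.0, lab_slope_sd=0.0, lab_intercept_sd=0.5,
                residual_sd=1e-9, transform="log1p", seed=3)
        t = ml.simulate(c)
        y = np.log1p(t["response"])
        for _, g in t.assign(y=y).groupby("lab_id"):
            means = g.groupby("treatment")["y"].mean()
            assert np.allclose(means.iloc[0], means.iloc[1], atol=1e-6)
            assert abs(means.iloc[0] - 2.0) < 2.0     # alpha_j = 2 + N(0, 0.25)

    def test_ceiling_truncates_raw_scale(self):
        c = cfg(alpha=7.0, beta=0.0, residual_sd=0.5, transform="log1p",
                response_ceiling=600.0)
        t = ml.simulate(c)
        assert t["response"].max() <= 600.0
        assert (t["response"] == 600.0).any()        # alpha above log(601)

    def test_mean_fitted_contrast_recovers_generating_beta(self):
        # simulation-consistency: average OLS contrast over replicates ~ beta
        c0 = ml.default_scenario("gaussian_two_group")
        spec = ml.spec_for_scenario(c0)
        ests = []
        for s in range(120):
            c = SimulationConfig.from_dict({**c0.to_dict(),
                                            "seed": s, "n_labs": 1,
                                            "lab_intercept_sd": 0.0})
            ests.append(ml.fit_gaussian_model(ml.simulate(c), spec).estimate)
        se_mc = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - c0.beta) < 3 * se_mc + 0.02


class TestBinaryArchetype:
    def test_symmetric_logit_gives_half_choice_rate(self):
        c = cfg(archetype="binary_repeated_choice", n_labs=1,
                units_per_group_per_lab=100, n_timepoints=50,
                alpha=0.0, beta=0.0, lab_intercept_sd=0.0, unit_re_sd=0.0,
                availability_prob=1.0)
        t = ml.simulate(c)
        n = len(t)
        assert n == 10_000
        frac = t["response"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_availability_thinning_matches_study_rate(self):
        # 185 individuals x 50 scheduled observations, 15.1% scorable
        c = cfg(archetype="binary_repeated_choice", n_labs=1,
                units_per_group_per_lab=93, n_timepoints=50,
                availability_prob=0.151, unit_re_sd=1.0)
        t = ml.simulate(c)
        n_sched = len(t)
        frac = t["scorable"].mean()
        assert abs(frac - 0.151) < 3 * np.sqrt(0.151 * 0.849 / n_sched)
        assert t.loc[~t.scorable, "response"].isna().all()
        assert t.loc[t.scorable, "response"].notna().all()

    def test_unit_heterogeneity_creates_overdispersion(self):
        c = cfg(archetype="binary_repeated_choice", n_labs=1,
                units_per_group_per_lab=150, n_timepoints=20,
                alpha=0.0, beta=0.0, unit_re_sd=2.0, availability_prob=1.0)
        t = ml.simulate(c)
        unit_means = t.groupby("unit_id")["response"].mean()
        p = t["response"].mean()
        binomial_var = p * (1 - p) / 20
        assert unit_means.var(ddof=1) > 3 * binomial_var


class TestDishArchetype:
    def test_total_individual_positions(self):
        # 214 dishes x 14 time points x 3 individuals = 8,988 positions
        c = cfg(archetype="dish_proportion", n_labs=1,
                units_per_group_per_lab=107, n_timepoints=14, group_size=3,
                availability_prob=1.0, unit_re_sd=0.0, olre_sd=0.0)
        t = ml.simulate(c)
        assert t["trials"].sum() == 3 * 214 * 14 == 8988

    def test_adult_availability_thinning(self):
        c = cfg(archetype="dish_proportion", n_labs=1,
                units_per_group_per_lab=100, n_timepoints=14, group_size=3,
                availability_prob={"larvae": 1.0, "adult": 0.334},
                treatment_levels=("larvae", "adult"))
        t = ml.simulate(c)
        adults = t[t.treatment == "adult"]
        n_slots = 3 * len(adults)
        frac = adults["trials"].sum() / n_slots
        assert abs(frac - 0.334) < 3 * np.sqrt(0.334 * 0.666 / n_slots)
        assert (t.loc[t.treatment == "larvae", "trials"] == 3).all()

    def test_successes_bounded_by_trials(self):
        t = ml.simulate(ml.default_scenario("dish_proportion", seed=2))
        assert (t["successes"] <= t["trials"]).all()
        assert (t["scorable"] == (t["trials"] > 0)).all()


def test_lab_slope_heterogeneity_inflates_contrast_variance():
    """Across many labs, var(per-lab contrast) ~ lab_slope_sd^2 + sampling
    variance; averaged over simulation replicates to tame MC noise."""
    slope_sd, resid, n, n_labs, n_seeds = 0.5, 1.0, 30, 150, 10
    observed = []
    for seed in range(n_seeds):
        c = cfg(n_labs=n_labs, units_per_group_per_lab=n, beta=1.0,
                lab_slope_sd=slope_sd, lab_intercept_sd=0.3, residual_sd=resid,
                transform="none", response_ceiling=None, alpha=50.0, seed=seed)
        t = ml.simulate(c)
        contrasts = (t.groupby(["lab_id", "treatment"])["response"].mean()
                       .unstack().pipe(lambda d: d["treated"] - d["control"]))
        observed.append(contrasts.var(ddof=1))
    expected = slope_sd ** 2 + 2 * resid ** 2 / n
    se_mean = expected * np.sqrt(2.0 / (n_labs - 1)) / np.sqrt(n_seeds)
    assert abs(np.mean(observed) - expected) < 3 * se_mean
    # and the heterogeneous variance clearly exceeds the homogeneous one
    assert np.mean(observed) > 2 * resid ** 2 / n


class TestValidation:
    @pytest.mark.parametrize("bad", [
        dict(lab_slope_sd=-0.1), dict(n_labs=0), dict(availability_prob=0.0),
        dict(availability_prob=1.5), dict(residual_sd=0.0),
        dict(response_ceiling=-5.0), dict(transform="cube"),
        dict(archetype="poisson_counts"),
        dict(treatment_levels=("a", "b", "c")),
    ])
    def test_bad_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            cfg(**bad)

    def test_archetype_dispatch_mismatch(self):
        with pytest.raises(ValueError):
            ml.simulate_binary_choice_experiment(cfg())

    def test_yaml_round_trip(self, tmp_path):
        c = ml.default_scenario("dish_proportion", seed=9)
        p = tmp_path / "scenario.yaml"
        c.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == c
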