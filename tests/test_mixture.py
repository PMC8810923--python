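import numpy as np
import pandas as pd
import pytest

from slopehunter import (EMConfig, SelectionConfig, bootstrap_se, em_fit,
                         hunt_slope, loglikelihood, mixture_draws,
                         preset_scenario, select_target_component,
                         simulate_summary)
from slopehunter.mixture import MixtureParams
from slopehunter.selection import EstimationError


def line_table(slope=0.5, n=60, se=0.001):
    x = np.linspace(-0.05, 0.05, n)
    return pd.DataFrame({"snp": [f"s{i}" for i in range(n)],
                         "beta_I": x, "se_I": se,
                         "beta_P": slope * x, "se_P": se})


class TestEmFit:
    def test_degenerate_line_recovers_slope_and_full_weight(self):
        fit = em_fit(line_table(0.5), EMConfig(seed=0, bootstrap_B=0))
        assert fit.b1 == pytest.approx(0.5, abs=1e-6)
        assert fit.params.pi1 > 0.99

    def test_loglik_trace_nondecreasing(self):
        for seed in range(4):
            df = mixture_draws(400, b1=-0.4, pi1=0.6, s_i2=7e-4,
                               sigma_ip=1e-4, sigma_p2=5e-4, noise=0.006,
                               seed=seed)
            fit = em_fit(df, EMConfig(seed=seed, bootstrap_B=0, n_restarts=4))
            diffs = np.diff(fit.loglik_trace)
            assert diffs.min() > -1e-8

    def test_parameter_recovery_within_monte_carlo_error(self):
        # draws from the two-component model; oracle = truth of the draw
        b1s = []
        for seed in range(12):
            df = mixture_draws(5000, b1=-0.4, pi1=0.6, s_i2=7e-4,
                               sigma_ip=0.3 * np.sqrt(7e-4 * 5e-4),
                               sigma_p2=5e-4, noise=0.006, seed=seed)
            fit = em_fit(df, EMConfig(seed=seed, bootstrap_B=0, n_restarts=6))
            b1s.append(fit.b1)
        mc_se = np.std(b1s, ddof=1) / np.sqrt(len(b1s))
        assert abs(np.mean(b1s) - (-0.4)) < 3 * mc_se

    def test_scale_equivariance_in_beta_P(self):
        df = mixture_draws(500, b1=0.5, pi1=0.7, s_i2=1e-3, sigma_ip=1e-4,
                           sigma_p2=4e-4, noise=0.005, seed=3)
        f0 = em_fit(df, EMConfig(seed=0, bootstrap_B=0))
        d2 = df.copy()
        d2["beta_P"] *= 2.0
        d2["se_P"] *= 2.0
        f2 = em_fit(d2, EMConfig(seed=0, bootstrap_B=0))
        assert f2.b1 == pytest.approx(2.0 * f0.b1, rel=1e-5)

    def test_scale_equivariance_in_beta_I(self):
        df = mixture_draws(500, b1=0.5, pi1=0.7, s_i2=1e-3, sigma_ip=1e-4,
                           sigma_p2=4e-4, noise=0.005, seed=3)
        f0 = em_fit(df, EMConfig(seed=0, bootstrap_B=0))
        d2 = df.copy()
        d2["beta_I"] *= 2.0
        d2["se_I"] *= 2.0
        f2 = em_fit(d2, EMConfig(seed=0, bootstrap_B=0))
        assert f2.b1 == pytest.approx(0.5 * f0.b1, rel=1e-5)

    def test_sign_symmetry(self):
        df = mixture_draws(500, b1=0.5, pi1=0.7, s_i2=1e-3, sigma_ip=1e-4,
                           sigma_p2=4e-4, noise=0.005, seed=3)
        f0 = em_fit(df, EMConfig(seed=0, bootstrap_B=0))
        d2 = df.copy()
        d2["beta_P"] *= -1.0
        f2 = em_fit(d2, EMConfig(seed=0, bootstrap_B=0))
        assert f2.b1 == pytest.approx(-f0.b1, rel=1e-5)

    def test_responsibilities_in_unit_interval(self):
        df = mixture_draws(300, b1=-0.3, pi1=0.5, s_i2=1e-3, sigma_ip=0.0,
                           sigma_p2=6e-4, noise=0.005, seed=1)
        fit = em_fit(df, EMConfig(seed=1, bootstrap_B=0, n_restarts=4))
        assert np.all(fit.responsibilities >= 0)
        assert np.all(fit.responsibilities <= 1)

    def test_determinism_given_seed(self):
        df = mixture_draws(400, b1=-0.4, pi1=0.6, s_i2=7e-4, sigma_ip=2e-4,
                           sigma_p2=5e-4, noise=0.006, seed=9)
        f1 = em_fit(df, EMConfig(seed=42, bootstrap_B=0))
        f2 = em_fit(df, EMConfig(seed=42, bootstrap_B=0))
        assert f1.b1 == f2.b1
        assert np.array_equal(f1.responsibilities, f2.responsibilities)

    def test_too_few_snps_raises(self):
        with pytest.raises(EstimationError):
            em_fit(line_table(n=10), EMConfig(bootstrap_B=0))

    def test_degenerate_beta_I_raises(self):
        df = line_table()
        df["beta_I"] = 0.0
        with pytest.raises(EstimationError):
            em_fit(df, EMConfig(bootstrap_B=0))


class TestLoglikelihood:
    def test_single_point_matches_closed_form(self):
        params = MixtureParams(b1=0.5, pi1=0.6, var_bI_1=1e-3, var_bI_2=1e-3,
                               cov_IP=2e-4, var_bP_direct=5e-4, tau2=1e-5)
        df = pd.DataFrame({"snp": ["s0"], "beta_I": [0.0], "se_I": [0.003],
                           "beta_P": [0.0], "se_P": [0.003]})

        def biv_density(x, y, v, slope, cv):
            return (np.exp(-0.5 * x * x / v) / np.sqrt(2 * np.pi * v)
                    * np.exp(-0.5 * (y - slope * x) ** 2 / cv)
                    / np.sqrt(2 * np.pi * cv))

        expected = np.log(
            0.6 * biv_density(0, 0, params.var_bI_1, params.b1, params.tau2)
            + 0.4 * biv_density(0, 0, params.var_bI_2, params.slope2,
                                params.cond_var_2))
        assert loglikelihood(params, df) == pytest.approx(expected, rel=1e-12)

    def test_pi_one_collapses_to_component_one(self):
        df = mixture_draws(50, b1=0.3, pi1=1.0, s_i2=1e-3, sigma_ip=0.0,
                           sigma_p2=1e-4, noise=0.004, seed=2)
        params = MixtureParams(b1=0.3, pi1=1.0, var_bI_1=1e-3, var_bI_2=1e-3,
                               cov_IP=0.0, var_bP_direct=1e-4, tau2=1.6e-5)
        x = df["beta_I"].to_numpy()
        y = df["beta_P"].to_numpy()
        comp1 = np.sum(
            -0.5 * np.log(2 * np.pi * 1e-3) - 0.5 * x**2 / 1e-3
            - 0.5 * np.log(2 * np.pi * 1.6e-5) - 0.5 * (y - 0.3 * x) ** 2 / 1.6e-5)
        assert loglikelihood(params, df) == pytest.approx(comp1, rel=1e-12)

    def test_em_solution_at_least_as_good_as_any_restart_init(self):
        df = mixture_draws(300, b1=-0.4, pi1=0.6, s_i2=7e-4, sigma_ip=2e-4,
                           sigma_p2=5e-4, noise=0.006, seed=5)
        fit = em_fit(df, EMConfig(seed=5, bootstrap_B=0, n_restarts=6))
        start = MixtureParams(b1=-0.1, pi1=0.5, var_bI_1=7e-4, var_bI_2=7e-4,
                              cov_IP=0.0, var_bP_direct=1e-3, tau2=4e-5)
        assert fit.loglik_trace[-1] >= loglikelihood(start, df)


class TestSelectTargetComponent:
    def test_larger_weight_wins_under_equal_variances(self):
        assert select_target_component([0.7, 0.3], [1e-3, 1e-3],
                                       [1e-5, 1e-4]) == 0

    def test_variance_share_beats_raw_weight(self):
        # 0.3 * 7e-4 > 0.7 * 1e-4
        assert select_target_component([0.3, 0.7], [7e-4, 1e-4],
                                       [1e-5, 1e-5]) == 0

    def test_tie_breaks_toward_tighter_line(self):
        assert select_target_component([0.5, 0.5], [1e-3, 1e-3],
                                       [1e-4, 1e-5]) == 1

    def test_small_but_strong_cluster_recovered(self):
        # 1% of SNPs affecting I only with large effects vs 9% affecting
        # both: the I-only cluster must be identified in >= 95% of runs
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            for rho in (0.9, 0.0):
                study = simulate_summary(
                    preset_scenario("s1", rho_d=rho, seed=seed * 311 + 13))
                fit = hunt_slope(study.sumstats,
                                 em_cfg=EMConfig(seed=seed, bootstrap_B=0))
                if abs(fit.b1 - study.realized_slope) < 0.15:
                    hits += 1
        assert hits >= 0.95 * 2 * n_runs


class TestBootstrap:
    def test_degenerate_line_gives_zero_se(self):
        df = line_table(0.5)
        cfg = EMConfig(seed=0, bootstrap_B=100)
        fit = em_fit(df, cfg)
        se, ci, frac = bootstrap_se(df, cfg, fit)
        assert se < 1e-6
        assert ci[0] <= fit.b1 <= ci[1]

    def test_se_tracks_sampling_distribution(self):
        # bootstrap SE vs empirical SD of the estimator over fresh draws
        def draw(seed):
            return mixture_draws(800, b1=-0.4, pi1=0.65, s_i2=7e-4,
                                 sigma_ip=2.5e-4, sigma_p2=5e-4, noise=0.006,
                                 seed=seed)
        fresh = []
        for seed in range(60):
            fit = em_fit(draw(1000 + seed),
                         EMConfig(seed=seed, bootstrap_B=0, n_restarts=4))
            fresh.append(fit.b1)
        empirical_sd = np.std(fresh, ddof=1)

        df = draw(7)
        cfg = EMConfig(seed=7, bootstrap_B=500, n_restarts=4)
        fit = em_fit(df, cfg)
        se, _, _ = bootstrap_se(df, cfg, fit)
        assert se == pytest.approx(empirical_sd, rel=0.35)

    def test_ci_contains_point_estimate_on_separated_data(self):
        df = mixture_draws(600, b1=-0.5, pi1=0.7, s_i2=1e-3, sigma_ip=8e-4,
                           sigma_p2=8e-4, noise=0.004, seed=11)
        cfg = EMConfig(seed=11, bootstrap_B=200)
        fit = em_fit(df, cfg)
        se, ci, _ = bootstrap_se(df, cfg, fit)
        assert ci[0] <= fit.b1 <= ci[1]

    def test_bootstrap_deterministic(self):
        df = mixture_draws(300, b1=-0.4, pi1=0.6, s_i2=7e-4, sigma_ip=2e-4,
                           sigma_p2=5e-4, noise=0.006, seed=3)
        cfg = EMConfig(seed=3, bootstrap_B=100, n_restarts=2)
        fit = em_fit(df, cfg)
        a = bootstrap_se(df, cfg, fit)
        b = bootstrap_se(df, cfg, fit)
        assert a == b


class TestHuntSlope:
    def test_recovers_slope_on_correlated_scenario(self):
        study = simulate_summary(preset_scenario("fig5b", seed=5))
        fit = hunt_slope(study.sumstats, em_cfg=EMConfig(seed=5, bootstrap_B=0))
        assert fit.b1 == pytest.approx(study.realized_slope, abs=0.1)

    def test_lambda_one_absorbs_null_mass(self):
        # with every SNP retained, the target component absorbs the null
        # cluster near the origin, so its weight approaches
        # pi_GI + pi_null = 0.90 (the slope itself degrades at such a loose
        # threshold: the null blob has no leverage along the line, which is
        # why the method defaults to a strict selection threshold)
        study = simulate_summary(preset_scenario("sc2", rho_d=0.4, seed=21))
        fit = hunt_slope(study.sumstats, SelectionConfig(lam=1.0),
                         EMConfig(seed=21, bootstrap_B=0))
        assert fit.params.pi1 == pytest.approx(0.90, abs=0.08)

    def test_no_snp_passing_threshold_raises(self):
        t = line_table()
        t["p_I"] = 0.5
        with pytest.raises(EstimationError):
            hunt_slope(t, SelectionConfig(lam=1e-3), EMConfig(bootstrap_B=0))

    def test_bootstrap_attached_when_requested(self):
        study = simulate_summary(preset_scenario("fig5a", seed=2))
        fit = hunt_slope(study.sumstats,
                         em_cfg=EMConfig(seed=2, bootstrap_B=100,
                                         n_restarts=4))
        assert fit.se_b1 is not None and fit.se_b1 > 0
        assert fit.ci_b1[0] < fit.b1 < fit.ci_b1[1]

    def test_serialisation_roundtrip(self, tmp_path):
        import json
        study = simulate_summary(preset_scenario("fig5a", seed=3))
        fit = hunt_slope(study.sumstats, em_cfg=EMConfig(seed=3, bootstrap_B=0))
        fit.to_json(tmp_path / "fit.json")
        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["b1"] == pytest.approx(fit.b1)
        assert d["converged"] is True
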