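"""SSR, chi-square assessment, profile CIs, normalization."""

import math

import numpy as np
import pytest
from scipy import stats

from picoflux import synthetic as syn
from picoflux.fit import (
    FitModel,
    chi_square_range,
    fit_fluxes,
    normalize_to_co2,
    profile_ci_objective,
    ssr,
)
from picoflux.network import FluxVector
from picoflux.simulate import simulate_labeling


class TestSSR:
    def test_zero_for_perfect_fit(self, scn_small, emunet_small):
        meas, _ = syn.generate_experiment(
            syn.scenario("tg2-small", noise_sd=0.0), emunet=emunet_small
        )
        scn = scn_small
        sim = simulate_labeling(
            scn.network, emunet_small, scn.fluxes, scn.pools, scn.label,
            times=scn.times, natural_abundance=scn.natural_abundance,
        )
        assert ssr(sim, meas) < 1e-18

    def test_one_two_sigma_residual_counts_four(self, scn_small, emunet_small):
        meas, _ = syn.generate_experiment(
            syn.scenario("tg2-small", noise_sd=0.0), emunet=emunet_small
        )
        frame = meas.frame.copy()
        sd = 0.02
        frame["sd"] = sd
        frame.loc[0, "mole_fraction"] += 2 * sd  # one residual of exactly 2 SD
        meas2 = type(meas)(frame=frame, growth_rate=meas.growth_rate)
        scn = scn_small
        sim = simulate_labeling(
            scn.network, emunet_small, scn.fluxes, scn.pools, scn.label,
            times=scn.times, natural_abundance=scn.natural_abundance,
        )
        assert ssr(sim, meas2, sd_floor=0.0) == pytest.approx(4.0, abs=1e-9)

    def test_ssr_at_truth_is_chi_square_distributed(self, scn_small, emunet_small):
        """Monte-Carlo: mean of SSR over Gaussian draws ~ number of residuals."""
        cfg = syn.scenario_fit_config(scn_small, starts=1)
        vals = []
        n = None
        for rep in range(200):
            meas, _ = syn.generate_experiment(
                scn_small, emunet=emunet_small, seed=3000 + rep, truncate=False
            )
            model = FitModel(scn_small.network, emunet_small, meas, scn_small.label, cfg)
            x = model.pack(scn_small.fluxes, scn_small.pools, scn_small.dilution)
            vals.append(model.ssr_at(x))
            n = model._n_obs
        mean = np.mean(vals)
        # mean of chi2(n) is n; SE of the mean over 200 draws is sqrt(2n/200)
        assert abs(mean - n) < 4 * math.sqrt(2 * n / 200)

    def test_missing_simulated_counterpart_raises(self, scn_small, emunet_small):
        meas, _ = syn.generate_experiment(scn_small, emunet=emunet_small, seed=1)
        frame = meas.frame.copy()
        frame.loc[0, "fragment"] = "GHOST{1,2}"
        bad = type(meas)(frame=frame)
        scn = scn_small
        sim = simulate_labeling(
            scn.network, emunet_small, scn.fluxes, scn.pools, scn.label,
            times=scn.times,
        )
        from picoflux.fit import FitError

        with pytest.raises(FitError, match="GHOST"):
            ssr(sim, bad)


class TestChiSquareRange:
    def test_df10_alpha05_quantiles(self):
        lo, hi = chi_square_range(10, 0.05)
        assert lo == pytest.approx(3.247, abs=1e-3)
        assert hi == pytest.approx(20.483, abs=1e-3)

    def test_collapses_toward_median_as_alpha_grows(self):
        lo, hi = chi_square_range(1, 0.999)
        median = stats.chi2.ppf(0.5, 1)
        assert abs(lo - median) < 0.01 and abs(hi - median) < 0.01

    def test_interval_mean_near_df_for_large_df(self):
        lo, hi = chi_square_range(500, 0.05)
        assert lo < 500 < hi
        assert (lo + hi) / 2 == pytest.approx(500, rel=0.01)

    @pytest.mark.parametrize("df,alpha", [(0, 0.05), (3, 0.0), (3, 1.0), (2.5, 0.05)])
    def test_invalid_inputs_rejected(self, df, alpha):
        with pytest.raises(ValueError):
            chi_square_range(df, alpha)


class TestProfileGeneric:
    def test_linear_gaussian_profile_matches_analytic_se(self):
        """For a linear model with Gaussian errors the profile CI equals the
        closed-form +-1.96 SE interval (to 2%)."""
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), np.linspace(0, 1, 40)])
        beta_true = np.array([1.0, 2.0])
        sigma = 0.1
        y = X @ beta_true + rng.normal(0, sigma, 40)

        def objective(beta):
            r = (X @ beta - y) / sigma
            return float(r @ r)

        # analytic solution and SE of beta_1
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        cov = np.linalg.inv(X.T @ X) * sigma**2
        se = math.sqrt(cov[1, 1])

        def refit(idx, value, x_start):
            # closed-form re-optimization of the other coordinate
            other = 1 - idx
            resid = y - X[:, idx] * value
            b = float(X[:, other] @ resid / (X[:, other] @ X[:, other]))
            x = x_start.copy()
            x[idx] = value
            x[other] = b
            return objective(x), x

        lo = np.array([-10.0, -10.0])
        hi = np.array([10.0, 10.0])
        lower, upper = profile_ci_objective(
            objective, beta_hat, 1, (lo, hi), refit, step_frac=0.05, max_steps=30
        )
        assert lower == pytest.approx(beta_hat[1] - 1.96 * se, rel=0.02)
        assert upper == pytest.approx(beta_hat[1] + 1.96 * se, rel=0.02)

    def test_flat_objective_reports_unbounded(self):
        def objective(x):
            return 1.0

        def refit(idx, value, x_start):
            x = x_start.copy()
            x[idx] = value
            return 1.0, x

        lo, hi = np.array([-math.inf]), np.array([math.inf])
        lower, upper = profile_ci_objective(
            objective, np.array([0.5]), 0, (lo, hi), refit, max_steps=10
        )
        assert lower == -math.inf and upper == math.inf


class TestNormalization:
    def test_uptake_maps_to_exactly_100(self):
        fluxes = FluxVector(net={"src": 7.3, "a": 1.0})
        norm = normalize_to_co2(fluxes, 7.3)
        assert norm.net["src"] == pytest.approx(100.0, abs=1e-12)

    def test_scale_invariance(self):
        fluxes = FluxVector(net={"src": 2.0, "a": 0.5, "b": -0.25})
        n1 = normalize_to_co2(fluxes, 2.0)
        n2 = normalize_to_co2(fluxes.scaled(2.0), 4.0)
        for k in fluxes.net:
            assert n1.net[k] == pytest.approx(n2.net[k], abs=1e-12)

    def test_flux_ratios_preserved(self):
        fluxes = FluxVector(net={"src": 9.59, "x": 3.17, "y": 1.11})
        norm = normalize_to_co2(fluxes, 9.59)
        assert norm.net["x"] / norm.net["y"] == pytest.approx(3.17 / 1.11, rel=1e-12)
        assert norm.factor == pytest.approx(100.0 / 9.59)

    def test_nonpositive_uptake_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_co2(FluxVector(net={"src": 0.0}), 0.0)


class TestFitMachinery:
    def test_warm_start_keeps_truth(self, scn_small, emunet_small):
        """Fitting noise-free data from the true parameter vector terminates
        at the truth with SSR ~ 0."""
        clean = syn.scenario("tg2-small", noise_sd=0.0)
        meas, _ = syn.generate_experiment(clean, emunet=emunet_small)
        cfg = syn.scenario_fit_config(clean, starts=1, seed=0, max_nfev=20)
        model = FitModel(clean.network, emunet_small, meas, clean.label, cfg)
        x0 = model.pack(clean.fluxes, clean.pools, clean.dilution)
        fit = fit_fluxes(clean.network, emunet_small, meas, cfg, label=clean.label, x0=x0)
        assert fit.ssr < 1e-10
        for rid, v in clean.fluxes.net.items():
            assert fit.fluxes.net[rid] == pytest.approx(v, rel=1e-6, abs=1e-8)
        assert fit.co2_uptake == pytest.approx(clean.co2_uptake, rel=1e-6)

    def test_multistart_determinism(self, scn_small, emunet_small, small_measurements):
        meas, _ = small_measurements
        cfg = syn.scenario_fit_config(scn_small, starts=2, seed=42, max_nfev=8)
        f1 = fit_fluxes(scn_small.network, emunet_small, meas, cfg, label=scn_small.label)
        f2 = fit_fluxes(scn_small.network, emunet_small, meas, cfg, label=scn_small.label)
        assert f1.ssr == f2.ssr
        assert np.array_equal(f1.x, f2.x)
        assert f1.start_trace == f2.start_trace

    def test_best_ssr_is_minimum_over_starts(self, scn_small, emunet_small, small_measurements):
        meas, _ = small_measurements
        cfg = syn.scenario_fit_config(scn_small, starts=3, seed=42, max_nfev=8)
        fit = fit_fluxes(scn_small.network, emunet_small, meas, cfg, label=scn_small.label)
        assert fit.ssr == pytest.approx(min(s for _, s in fit.start_trace))

    def test_df_counts_every_fitted_parameter(self, scn_small, emunet_small, small_measurements):
        meas, _ = small_measurements
        cfg = syn.scenario_fit_config(scn_small, starts=1, seed=0, max_nfev=5)
        model = FitModel(scn_small.network, emunet_small, meas, scn_small.label, cfg)
        fit = fit_fluxes(scn_small.network, emunet_small, meas, cfg,
                         label=scn_small.label,
                         x0=model.pack(scn_small.fluxes, scn_small.pools, {}))
        assert fit.df == meas.n_observations - model.n_params
        lo, hi = fit.chi2_range
        assert lo == pytest.approx(stats.chi2.ppf(0.025, fit.df))
        assert hi == pytest.approx(stats.chi2.ppf(0.975, fit.df))
        assert "SSR = " in fit.summary()["ssr_bracket"]
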