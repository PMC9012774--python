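"""Expected-SFS solver, composite likelihood, optimisation and selection."""

import math

import numpy as np
import pytest

from rangeedge import (
    MODELS,
    SiteFrequencySpectrum,
    SizeHistory,
    expected_sfs,
    fold_sfs,
    format_selection_table,
    gof_parametric_bootstrap,
    loglik,
    model_selection,
    optimize,
    selection_table_from_loglik,
    simulate_coalescent_sfs,
    to_demographic_units,
)
from rangeedge.demography import round_half_up


class TestExpectedSfs:
    @pytest.mark.parametrize("n", [10, 70, 100])
    def test_constant_size_fixed_point(self, n):
        # every model collapses to the 1/i equilibrium when nu == 1
        xi = expected_sfs("two_epoch", [1.0, 0.7], n).values
        target = 1.0 / np.arange(1, n)
        assert np.max(np.abs(xi / target - 1.0)) < 1e-6

    def test_growth_with_zero_duration_is_constant_size(self):
        xi = expected_sfs("growth", [25.0, 1e-300], 20).values
        assert np.allclose(xi, 1.0 / np.arange(1, 20), rtol=1e-8)

    @pytest.mark.parametrize(
        "model,params,seed",
        [
            ("two_epoch", [25.0, 0.05], 21),
            ("growth", [25.0, 0.1], 22),
            ("three_epoch", [0.1, 5.0, 0.2, 0.1], 23),
        ],
    )
    def test_monte_carlo_oracle_agreement(self, model, params, seed):
        # independent coalescent simulation of the same size history
        n, theta, reps = 20, 10.0, 60_000
        hist = MODELS[model].history(np.asarray(params))
        mat = simulate_coalescent_sfs(hist, n, theta, reps, seed=seed, per_rep=True)
        mean = mat.mean(axis=0)
        se = mat.std(axis=0) / math.sqrt(reps)
        exp = theta * expected_sfs(model, params, n).values
        assert np.all(np.abs(mean - exp) < 3.5 * se)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            expected_sfs("two_epoch", [np.nan, 0.1], 10)
        with pytest.raises(ValueError):
            expected_sfs("two_epoch", [-1.0, 0.1], 10)
        with pytest.raises(ValueError):
            expected_sfs("two_epoch", [1.0, 0.1], 3)


class TestLoglik:
    def test_exact_moment_match_recovers_theta(self):
        xi = SiteFrequencySpectrum(8, 1.0 / np.arange(1, 8), kind="density")
        theta = 420.0
        obs = SiteFrequencySpectrum(8, theta * xi.values)
        ll, theta_hat = loglik(obs, xi)
        assert theta_hat == pytest.approx(theta)

    def test_closed_form_matches_grid_argmax(self, rng):
        xi = SiteFrequencySpectrum(10, expected_sfs("two_epoch", [5.0, 0.2], 10).values, kind="density")
        obs = SiteFrequencySpectrum(10, rng.poisson(300 * xi.values).astype(float))
        _, theta_hat = loglik(obs, xi)
        grid = np.linspace(0.5 * theta_hat, 1.5 * theta_hat, 200001)
        lls = [
            np.sum(obs.values * np.log(t * xi.values) - t * xi.values) for t in grid
        ]
        assert grid[int(np.argmax(lls))] == pytest.approx(theta_hat, abs=1e-2)

    def test_theta_hat_linear_in_counts(self):
        xi = SiteFrequencySpectrum(6, 1.0 / np.arange(1, 6), kind="density")
        obs = SiteFrequencySpectrum(6, np.array([10.0, 5.0, 3.0, 2.0, 1.0]))
        _, t1 = loglik(obs, xi)
        _, t2 = loglik(SiteFrequencySpectrum(6, 2 * obs.values), xi)
        assert t2 == pytest.approx(2 * t1)

    def test_mass_on_empty_class_gives_minus_infinity(self):
        xi = SiteFrequencySpectrum(6, np.array([1.0, 0.5, 0.0, 0.25, 0.2]), kind="density")
        obs = SiteFrequencySpectrum(6, np.array([3.0, 1.0, 2.0, 0.0, 0.0]))
        ll, _ = loglik(obs, xi)
        assert ll == -np.inf

    def test_mismatched_fold_state_rejected(self):
        xi = expected_sfs("two_epoch", [1.0, 0.1], 6)
        obs = fold_sfs(SiteFrequencySpectrum(6, np.ones(5)))
        with pytest.raises(ValueError):
            loglik(obs, xi)


class TestOptimize:
    def test_recovers_two_epoch_parameters(self, rng):
        xi = expected_sfs("two_epoch", [25.0, 0.1], 70)
        obs = SiteFrequencySpectrum(70, rng.poisson(500 * xi.values).astype(float))
        fit = optimize("two_epoch", obs, rounds=3, reps_per_round=20, maxiter=25, seed=1)
        assert fit.params[0] == pytest.approx(25.0, rel=0.5)
        assert fit.params[1] == pytest.approx(0.1, rel=0.5)
        assert fit.theta_hat == pytest.approx(500.0, rel=0.1)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_same_seed_identical_result(self, rng):
        xi = expected_sfs("growth", [5.0, 0.2], 20)
        obs = SiteFrequencySpectrum(20, rng.poisson(200 * xi.values).astype(float))
        a = optimize("growth", obs, rounds=2, reps_per_round=5, maxiter=15, seed=3)
        b = optimize("growth", obs, rounds=2, reps_per_round=5, maxiter=15, seed=3)
        assert np.array_equal(a.params, b.params)
        assert a.loglik == b.loglik

    def test_no_spurious_improvement_on_constant_size_data(self, rng):
        xi = expected_sfs("two_epoch", [1.0, 0.5], 30)  # truly constant
        obs = SiteFrequencySpectrum(30, rng.poisson(400 * xi.values).astype(float))
        const_ll, _ = loglik(
            obs, SiteFrequencySpectrum(30, 1.0 / np.arange(1, 30), kind="density")
        )
        fit = optimize("two_epoch", obs, rounds=3, reps_per_round=15, maxiter=25, seed=2)
        assert fit.loglik >= const_ll - 1e-6
        assert fit.loglik - const_ll < 2.0  # roughly chi^2 noise, not structure

    def test_nesting_three_epoch_contains_two_epoch(self, rng):
        xi = expected_sfs("two_epoch", [10.0, 0.15], 30)
        obs = SiteFrequencySpectrum(30, rng.poisson(300 * xi.values).astype(float))
        fit2 = optimize("two_epoch", obs, rounds=3, reps_per_round=15, maxiter=25, seed=4)
        nu, T = fit2.params
        embedded = [nu, nu, T / 2, T / 2]  # identical size path as the 2-epoch fit
        fit3 = optimize(
            "three_epoch", obs, rounds=2, reps_per_round=10, maxiter=25, seed=5,
            init_params=embedded,
        )
        assert fit3.loglik >= fit2.loglik - 1e-3

    def test_empty_observation_rejected(self):
        obs = SiteFrequencySpectrum(10, np.zeros(9))
        with pytest.raises(ValueError):
            optimize("two_epoch", obs, rounds=1, reps_per_round=1, seed=0)


class TestModelSelection:
    def test_table4_arithmetic_from_printed_inputs(self):
        table = selection_table_from_loglik(
            ["two_epoch", "growth", "bottlegrowth", "three_epoch"],
            [2, 2, 3, 4],
            [-35.38, -35.54, -35.43, -35.32],
        )
        fmt = format_selection_table(table)
        assert fmt["model"].tolist() == [
            "two_epoch", "growth", "bottlegrowth", "three_epoch"
        ]
        assert fmt["AIC"].tolist() == [74.76, 75.08, 76.86, 78.64]
        assert fmt["dAIC"].tolist() == [0.00, 0.32, 2.10, 3.88]
        assert fmt["rel_lik"].tolist() == [1.00, 0.85, 0.35, 0.14]
        assert fmt["wAIC"].tolist() == [0.43, 0.36, 0.15, 0.06]
        assert fmt["cum_wAIC"].tolist() == [0.43, 0.79, 0.94, 1.00]

    def test_single_model_weight_one(self):
        table = selection_table_from_loglik(["two_epoch"], [2], [-10.0])
        assert table["wAIC"].iloc[0] == pytest.approx(1.0)

    def test_equal_models_split_weight(self):
        table = selection_table_from_loglik(["a", "b"], [2, 2], [-5.0, -5.0])
        assert np.allclose(table["wAIC"], [0.5, 0.5])

    def test_weights_sum_to_one_and_cumulative_monotone(self):
        table = selection_table_from_loglik(
            ["a", "b", "c"], [2, 3, 4], [-8.0, -7.5, -7.4]
        )
        assert table["wAIC"].sum() == pytest.approx(1.0)
        assert (np.diff(table["cum_wAIC"]) >= 0).all()
        assert table["dAIC"].iloc[0] == 0.0

    def test_duplicate_model_names_rejected(self):
        with pytest.raises(ValueError):
            selection_table_from_loglik(["a", "a"], [2, 2], [-1.0, -2.0])

    def test_round_half_up_matches_print_convention(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.124, 2) == 0.12


class TestGof:
    def test_single_rep_report(self, rng):
        xi = expected_sfs("two_epoch", [10.0, 0.1], 20)
        obs = SiteFrequencySpectrum(20, rng.poisson(300 * xi.values).astype(float))
        fit = optimize("two_epoch", obs, rounds=2, reps_per_round=5, maxiter=20, seed=1)
        gof = gof_parametric_bootstrap(fit, obs, n_reps=1, seed=2, reps_per_round=3)
        assert gof.sim_logliks.shape == (1,)

    def test_seeded_determinism(self, rng):
        xi = expected_sfs("two_epoch", [10.0, 0.1], 20)
        obs = SiteFrequencySpectrum(20, rng.poisson(300 * xi.values).astype(float))
        fit = optimize("two_epoch", obs, rounds=2, reps_per_round=5, maxiter=20, seed=1)
        a = gof_parametric_bootstrap(fit, obs, n_reps=3, seed=7, reps_per_round=3)
        b = gof_parametric_bootstrap(fit, obs, n_reps=3, seed=7, reps_per_round=3)
        assert np.array_equal(a.sim_logliks, b.sim_logliks)


class TestDemographicUnits:
    def test_unit_check(self):
        from rangeedge.demography import FitResult, get_model

        model = get_model("two_epoch")
        fit = FitResult(model, np.array([2.0, 1.0]), 4.0, -1.0, 6.0, 10, False)
        units = to_demographic_units(fit, mu=1.0, L=1.0, gen_time=2.0)
        assert units.Nref == pytest.approx(1.0)
        assert units.times_years["T"] == pytest.approx(4.0)

    def test_doubling_L_halves_nref_and_years(self):
        from rangeedge.demography import FitResult, get_model

        model = get_model("two_epoch")
        fit = FitResult(model, np.array([25.0, 0.1]), 100.0, -1.0, 6.0, 70, True)
        u1 = to_demographic_units(fit, mu=7.7e-10, L=51_000, gen_time=2.0)
        u2 = to_demographic_units(fit, mu=7.7e-10, L=102_000, gen_time=2.0)
        assert u2.Nref == pytest.approx(u1.Nref / 2)
        assert u2.times_years["T"] == pytest.approx(u1.times_years["T"] / 2)
        assert u1.mu == 7.7e-10 and u1.gen_time == 2.0

    def test_zero_theta_rejected(self):
        from rangeedge.demography import FitResult, get_model

        fit = FitResult(get_model("growth"), np.array([2.0, 0.1]), 0.0, -1.0, 6.0, 10, False)
        with pytest.raises(ValueError):
            to_demographic_units(fit, mu=1e-9, L=1000, gen_time=2.0)
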