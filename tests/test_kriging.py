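"""Discrete-posterior Bayesian kriging: oracle equivalence, invariances,
sampling contracts and predictive identities."""

import numpy as np
import pandas as pd
import pytest

from ecokrige import (
    ObservationSet,
    ParameterGrid,
    VariogramParams,
    draw_posterior_samples,
    fit_discrete_posterior,
    krige_predict,
    log_marginal_posterior,
    parameter_summaries,
    predict_fixed_params,
    simulate_grf,
)
from ecokrige.errors import (
    DegenerateDataError,
    InvalidInputError,
    InvalidParameterError,
)
from ecokrige.geostat import pairwise_distances
from ecokrige.kriging import _cell_predictor


def quadrature_log_evidence(coords, y, phi, nu, n_beta=801, n_logs2=2001):
    """Brute-force evidence of one (phi, nu) cell by tensor quadrature over
    (beta, log sigma2), with flat beta and reciprocal sigma2 priors.  The
    beta grid is centered per sigma2 slice for accuracy; the integrand is
    evaluated directly from the Gaussian density.  Independent of the
    package's eigendecomposition route."""
    n = len(y)
    V = np.exp(-pairwise_distances(coords) / phi) + nu * np.eye(n)
    Vi = np.linalg.inv(V)
    ld = np.linalg.slogdet(V)[1]
    ones = np.ones(n)
    c = ones @ Vi @ ones
    b_center = (ones @ Vi @ y) / c
    u = np.linspace(-14.0, 14.0, n_beta)
    log_s2_grid = np.linspace(-18.0, 14.0, n_logs2)
    slice_logs = np.empty(n_logs2)
    for k, ls2 in enumerate(log_s2_grid):
        s2 = np.exp(ls2)
        beta = b_center + u * np.sqrt(s2 / c)
        resid = y[None, :] - beta[:, None]
        quad = np.einsum("bi,ij,bj->b", resid, Vi, resid)
        logf = -0.5 * quad / s2 - 0.5 * n * ls2 - 0.5 * ld - 0.5 * n * np.log(2 * np.pi)
        m = logf.max()
        slice_logs[k] = m + np.log(np.trapezoid(np.exp(logf - m), beta))
    m = slice_logs.max()
    return m + np.log(np.trapezoid(np.exp(slice_logs - m), log_s2_grid))


@pytest.fixture(scope="module")
def grid33():
    return ParameterGrid(np.array([20.0, 50.0, 100.0]), np.array([0.0, 0.2, 0.8]))


class TestDiscretePosterior:
    def test_matches_brute_force_quadrature(self, toy_obs, grid33):
        """Normalized 3x3 posterior agrees with (beta, sigma2) quadrature
        to better than 1e-6 relative."""
        post = fit_discrete_posterior(toy_obs, grid33)
        lev = np.array(
            [
                [
                    quadrature_log_evidence(toy_obs.coords, toy_obs.values, phi, nu)
                    for nu in grid33.nu_values
                ]
                for phi in grid33.phi_values
            ]
        )
        brute = np.exp(lev - lev.max())
        brute /= brute.sum()
        assert np.max(np.abs(brute / post.weights - 1)) < 1e-6

    def test_translation_and_scale_invariance(self, toy_obs, grid33):
        post = fit_discrete_posterior(toy_obs, grid33)
        shifted = ObservationSet(toy_obs.coords, toy_obs.values + 17.3)
        scaled = ObservationSet(toy_obs.coords, toy_obs.values * 4.2)
        assert np.allclose(
            post.weights, fit_discrete_posterior(shifted, grid33).weights, atol=1e-10
        )
        assert np.allclose(
            post.weights, fit_discrete_posterior(scaled, grid33).weights, atol=1e-10
        )

    def test_single_cell_has_probability_one(self, toy_obs):
        post = fit_discrete_posterior(
            toy_obs, ParameterGrid(np.array([40.0]), np.array([0.1]))
        )
        assert post.weights.shape == (1, 1)
        assert post.weights[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_weights_normalized(self, toy_obs, grid33):
        post = fit_discrete_posterior(toy_obs, grid33)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_log_marginal_matches_grid_fit(self, toy_obs, grid33):
        post = fit_discrete_posterior(toy_obs, grid33)
        single = np.array(
            [
                [log_marginal_posterior(toy_obs, phi, nu) for nu in grid33.nu_values]
                for phi in grid33.phi_values
            ]
        )
        w = np.exp(single - single.max())
        w /= w.sum()
        assert np.allclose(w, post.weights, rtol=1e-10)

    def test_degenerate_data_rejected(self):
        tiny = ObservationSet(np.array([[0.0, 0.0]]), np.array([1.0]))
        with pytest.raises(DegenerateDataError):
            fit_discrete_posterior(tiny, ParameterGrid(np.array([10.0]), np.array([0.0])))
        four = ObservationSet(
            np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
            np.array([0.0, 1.0, 2.0, 3.0]),
        )
        with pytest.raises(InvalidParameterError):
            log_marginal_posterior(four, -1.0, 0.0)

    def test_mode_recovery_across_replicates(self):
        """Simulating from a cell interior to a coarse grid, the posterior
        mode lands within one grid step of truth in a majority of 20
        replicates (range parameters are weakly identified, so the grid is
        deliberately coarse)."""
        grid = ParameterGrid(np.linspace(10, 200, 7), np.linspace(0, 0.5, 7))
        step_p = np.diff(grid.phi_values)[0]
        step_n = np.diff(grid.nu_values)[0]
        truth = VariogramParams(3.0, 1.5, 0.15, 60.0)
        hits = 0
        for s in range(20):
            r = np.random.default_rng(200 + s)
            coords = r.uniform(0, 300, (150, 2))
            y = truth.beta + simulate_grf(coords, truth, r)
            post = fit_discrete_posterior(ObservationSet(coords, y), grid)
            ip, iv = post.mode
            hits += (
                abs(grid.phi_values[ip] - truth.phi) <= step_p + 1e-9
                and abs(grid.nu_values[iv] - truth.nu) <= step_n + 1e-9
            )
        assert hits > 10


class TestPosteriorDraws:
    def test_determinism_given_seed(self, toy_obs, grid33):
        post = fit_discrete_posterior(toy_obs, grid33)
        d1 = draw_posterior_samples(post, 500, seed=42)
        d2 = draw_posterior_samples(post, 500, seed=42)
        pd.testing.assert_frame_equal(d1, d2)

    def test_cell_frequencies_converge_to_weights(self, sim_obs150):
        obs, _ = sim_obs150
        grid = ParameterGrid(np.linspace(20, 150, 8), np.linspace(0, 0.5, 8))
        post = fit_discrete_posterior(obs, grid)
        draws = draw_posterior_samples(post, 100_000, seed=7)
        emp = np.zeros(grid.shape)
        np.add.at(emp, (draws["i_phi"], draws["i_nu"]), 1.0)
        emp /= emp.sum()
        tv = 0.5 * np.abs(emp - post.weights).sum()
        assert tv < 0.02

    def test_sigma2_mean_matches_inverse_chi_square(self, sim_obs150):
        obs, _ = sim_obs150
        post = fit_discrete_posterior(
            obs, ParameterGrid(np.array([60.0]), np.array([0.1]))
        )
        draws = draw_posterior_samples(post, 200_000, seed=3)
        expected = post.s2[0, 0] / (post.df - 2)
        assert draws["sigma2"].mean() == pytest.approx(expected, rel=0.02)

    def test_nsr_in_unit_interval(self, toy_obs, grid33):
        post = fit_discrete_posterior(toy_obs, grid33)
        draws = draw_posterior_samples(post, 2000, seed=0)
        nsr = draws["tau2"] / (draws["tau2"] + draws["sigma2"])
        assert np.all((nsr >= 0) & (nsr <= 1))

    def test_explicit_sigma2_grid_mode(self, toy_obs):
        """With a discrete sigma2 axis the posterior concentrates near the
        analytic conditional's region and draws stay on the grid."""
        grid = ParameterGrid(
            np.array([20.0, 50.0, 100.0]),
            np.array([0.0, 0.2, 0.8]),
            sigma2_values=np.geomspace(1e-4, 1e4, 400),
        )
        post = fit_discrete_posterior(toy_obs, grid)
        assert post.weights.shape == (3, 3, 400)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-10)
        draws = draw_posterior_samples(post, 1000, seed=0)
        assert set(np.round(draws["sigma2"], 12)) <= set(
            np.round(grid.sigma2_values, 12)
        )
        # marginal over sigma2 close to the analytic (phi, nu) posterior
        analytic = fit_discrete_posterior(
            toy_obs, ParameterGrid(grid.phi_values, grid.nu_values)
        )
        assert np.max(np.abs(post.weights_phi_nu - analytic.weights)) < 0.02


class TestKrigePredict:
    def test_exact_interpolation_at_zero_nugget(self, sim_obs150):
        obs, truth = sim_obs150
        post = fit_discrete_posterior(
            obs, ParameterGrid(np.array([truth.phi]), np.array([0.0]))
        )
        pm = krige_predict(post, obs.coords[:6], n_draws=300, seed=1)
        assert np.allclose(pm.mean, obs.values[:6], atol=1e-8)
        assert np.all(pm.variance < 1e-10)

    def test_far_field_reverts_to_trend(self, sim_obs150):
        obs, truth = sim_obs150
        post = fit_discrete_posterior(
            obs, ParameterGrid(np.array([truth.phi]), np.array([0.0]))
        )
        far = np.array([[50_000.0, 50_000.0]])
        a, b, q = _cell_predictor(post, 0, 0, far)
        # per-draw conditional mean = a + b * beta -> beta_hat direction
        assert a[0] == pytest.approx(0.0, abs=1e-10)
        assert b[0] == pytest.approx(1.0, abs=1e-10)
        assert q[0] == pytest.approx(0.0, abs=1e-10)  # signal variance -> sigma2

    def test_matches_dense_conditional_gaussian(self, toy_obs):
        """Fixed-parameter predictions at 2 targets equal the brute-force
        conditional multivariate-Gaussian computation to 1e-8."""
        p = VariogramParams(beta=1.1, sigma2=0.8, tau2=0.08, phi=45.0)
        targets = np.array([[20.0, 20.0], [40.0, 5.0]])
        mean, var = predict_fixed_params(toy_obs, p, targets)
        # oracle: joint covariance of (data, signal at targets), conditioned
        n = toy_obs.n
        joint = np.vstack([toy_obs.coords, targets])
        d = pairwise_distances(joint)
        C_signal = p.sigma2 * np.exp(-d / p.phi)
        C = C_signal.copy()
        C[:n, :n] += p.tau2 * np.eye(n)
        c12 = C[:n, n:]
        mu_cond = p.beta + c12.T @ np.linalg.solve(
            C[:n, :n], toy_obs.values - p.beta
        )
        S_cond = C_signal[n:, n:] - c12.T @ np.linalg.solve(C[:n, :n], c12)
        assert np.allclose(mean, mu_cond, atol=1e-8)
        assert np.allclose(var, np.diag(S_cond), atol=1e-8)

    def test_cell_predictor_consistent_with_fixed_params(self, toy_obs):
        p = VariogramParams(beta=0.9, sigma2=1.0, tau2=0.2, phi=45.0)
        post = fit_discrete_posterior(
            toy_obs, ParameterGrid(np.array([p.phi]), np.array([p.nu]))
        )
        targets = np.array([[20.0, 20.0], [40.0, 5.0]])
        a, b, q = _cell_predictor(post, 0, 0, targets)
        mean, var = predict_fixed_params(toy_obs, p, targets)
        assert np.allclose(a + b * p.beta, mean, atol=1e-10)
        assert np.allclose(p.sigma2 * (1.0 - q), var, atol=1e-10)

    def test_mean_linear_in_data_at_fixed_cell(self, toy_obs):
        grid = ParameterGrid(np.array([45.0]), np.array([0.2]))
        targets = np.array([[15.0, 25.0], [33.0, 33.0]])
        y = toy_obs.values

        def mean_map(vals):
            post = fit_discrete_posterior(ObservationSet(toy_obs.coords, vals), grid)
            a, b, q = _cell_predictor(post, 0, 0, targets)
            return a  # data-dependent part of the conditional mean

        assert np.allclose(
            mean_map(2 * y) + mean_map(np.zeros(4)), 2 * mean_map(y), atol=1e-10
        )

    def test_observation_variance_exceeds_signal_variance(self, sim_obs150):
        obs, truth = sim_obs150
        p = VariogramParams(truth.beta, truth.sigma2, truth.tau2, truth.phi)
        targets = np.array([[10.0, 10.0], [150.0, 150.0], [299.0, 1.0]])
        _, v_sig = predict_fixed_params(obs, p, targets, predict_signal=True)
        _, v_obs = predict_fixed_params(obs, p, targets, predict_signal=False)
        assert np.all(v_obs >= v_sig)
        assert np.allclose(v_obs - v_sig, p.tau2, atol=1e-10)

    def test_map_variance_law_of_total_variance(self, sim_obs150):
        obs, truth = sim_obs150
        grid = ParameterGrid(np.linspace(30, 120, 5), np.linspace(0, 0.4, 5))
        post = fit_discrete_posterior(obs, grid)
        pm = krige_predict(post, np.array([[150.0, 150.0]]), n_draws=5000, seed=9)
        assert pm.variance[0] > 0
        assert np.isfinite(pm.mean[0])

    def test_invalid_targets_rejected(self, toy_obs, grid33):
        post = fit_discrete_posterior(toy_obs, grid33)
        with pytest.raises(InvalidInputError):
            krige_predict(post, np.array([[np.nan, 0.0]]), n_draws=10, seed=0)


class TestParameterSummaries:
    def test_point_mass_draws(self):
        draws = pd.DataFrame(
            {
                "phi": np.full(10, 60.0),
                "nu": np.full(10, 0.1),
                "sigma2": np.full(10, 1.5),
                "tau2": np.full(10, 0.15),
                "beta": np.full(10, 3.0),
            }
        )
        t = parameter_summaries(draws).table
        for par, val in [("beta", 3.0), ("phi", 60.0), ("sigma2", 1.5), ("tau2", 0.15)]:
            assert t.loc[par, "mean"] == pytest.approx(val)
            assert t.loc[par, "q05"] == pytest.approx(val)
            assert t.loc[par, "q95"] == pytest.approx(val)
        assert t.loc["nsr", "mean"] == pytest.approx(0.15 / 1.65)

    def test_quantiles_match_sorting_oracle(self, rng):
        x = rng.gamma(2.0, 1.0, 5001)
        draws = pd.DataFrame(
            {"phi": x, "nu": x, "sigma2": x, "tau2": x, "beta": x}
        )
        t = parameter_summaries(draws).table
        xs = np.sort(x)
        # order-statistic interpolation oracle (linear, as np.quantile default)
        for q, col in [(0.05, "q05"), (0.95, "q95")]:
            pos = q * (len(xs) - 1)
            lo, frac = int(pos), pos - int(pos)
            oracle = xs[lo] * (1 - frac) + xs[lo + 1] * frac if frac else xs[lo]
            assert t.loc["phi", col] == pytest.approx(oracle, rel=1e-12)
        assert t.loc["phi", "q05"] <= t.loc["phi", "q95"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(InvalidInputError):
            parameter_summaries(pd.DataFrame({"phi": [1.0], "nu": [0.1],
                                              "sigma2": [1.0], "tau2": [0.1],
                                              "beta": [0.0]}))


def test_duplicate_coordinates_merged_by_mean():
    coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
    values = np.array([1.0, 2.0, 3.0, 4.0])
    obs = ObservationSet(coords, values)
    assert obs.n == 3
    i = np.where((obs.coords == [0.0, 0.0]).all(axis=1))[0][0]
    assert obs.values[i] == pytest.approx(2.0)
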