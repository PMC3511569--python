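"""Discrete-grid Bayesian geostatistics: oracles, sampling, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.spatial.distance import cdist

from firekrige import (
    BayesianKriging,
    SimulationTruth,
    SpatialObservations,
    compute_posterior,
    conditional_krige,
    exp_correlation,
    log_marginal,
    loo_cross_validate,
    sample_posterior,
    simulate_field,
    summarize_draws,
)
from firekrige.kriging import PosteriorDraws

TOY_COORDS = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])


def toy_obs(y=(0.0, 1.0, 0.0)):
    return SpatialObservations(coords=TOY_COORDS, y=np.asarray(y), trend="constant")


def brute_posterior(obs, phi_grid, tau_grid):
    """Quadrature oracle: integrate N(y; Xb, s2 V) / s2 over (b, s2) per cell."""
    x = obs.X
    assert x.shape[1] == 1, "oracle implemented for intercept-only trend"
    d = cdist(obs.coords, obs.coords)
    n = obs.n

    ybar, yspan = float(obs.y.mean()), float(np.ptp(obs.y)) + 1.0

    def cell(phi, tau):
        v = np.exp(-d / phi) + tau * np.eye(n)
        vi = np.linalg.inv(v)
        ld = np.linalg.slogdet(v)[1]

        def integrand(logs2, beta):
            s2 = np.exp(logs2)
            r = obs.y - beta
            return np.exp(-0.5 * (n * np.log(2 * np.pi * s2) + ld + r @ vi @ r / s2))

        # bounds centred on the data keep the adaptive rule on the peak
        val, _ = integrate.dblquad(
            integrand,
            ybar - 30 * yspan, ybar + 30 * yspan,
            2 * np.log(yspan) - 30, 2 * np.log(yspan) + 12,
            epsabs=1e-14, epsrel=1e-11,
        )
        return val

    mass = np.array([[cell(p, t) for t in tau_grid] for p in phi_grid])
    return mass / mass.sum()


class TestExpCorrelation:
    def test_known_values(self):
        assert exp_correlation(0.0, 2.0) == 1.0
        assert exp_correlation(2.0, 2.0) == pytest.approx(np.exp(-1))
        # at the nominal range 3*phi the correlation is ~0.05
        assert exp_correlation(6.0, 2.0) == pytest.approx(np.exp(-3), abs=1e-12)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            exp_correlation(1.0, 0.0)
        with pytest.raises(ValueError):
            exp_correlation(-1.0, 2.0)

    @given(
        h=st.floats(min_value=0.01, max_value=100.0),
        dh=st.floats(min_value=0.01, max_value=10.0),
        phi=st.floats(min_value=0.5, max_value=50.0),
        dphi=st.floats(min_value=0.01, max_value=10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_monotone_in_h_and_inverse_phi(self, h, dh, phi, dphi):
        assert exp_correlation(h + dh, phi) < exp_correlation(h, phi)
        assert exp_correlation(h, phi) < exp_correlation(h, phi + dphi)


class TestGridPosterior:
    def test_matches_quadrature_oracle_on_toys(self):
        phi_grid = np.array([0.5, 1.0, 2.0])
        tau_grid = np.array([0.1, 1.0])
        for y in ([0.0, 1.0, 0.0], [1.0, 2.0, 4.0], [-1.0, 0.5, 0.2]):
            obs = toy_obs(y)
            grid = compute_posterior(obs, phi_grid, tau_grid)
            oracle = brute_posterior(obs, phi_grid, tau_grid)
            tv = 0.5 * np.abs(grid.mass - oracle).sum()
            assert tv < 1e-4, f"y={y}: TV {tv}"

    def test_identical_parameters_identical_log_density(self):
        obs = toy_obs()
        assert log_marginal(obs, 1.3, 0.4) == log_marginal(obs, 1.3, 0.4)

    def test_huge_nugget_approaches_iid_marginal(self):
        # the marginal is invariant to V -> cV, so tau -> inf makes
        # V/(1+tau) -> I and the value converges to the iid closed form
        obs = toy_obs([1.0, 3.0, 2.0])
        x, y = obs.X, obs.y
        n, p = x.shape
        bh = np.linalg.lstsq(x, y, rcond=None)[0]
        rss = float((y - x @ bh) @ (y - x @ bh))
        iid = -0.5 * np.linalg.slogdet(x.T @ x)[1] - 0.5 * (n - p) * np.log(rss)
        big = log_marginal(obs, 1.0, 1e8)
        assert big == pytest.approx(iid, abs=1e-6)
        # phi no longer matters in the iid limit
        assert big == pytest.approx(log_marginal(obs, 2.5, 1e8), abs=1e-6)

    def test_single_cell_grid_has_mass_one(self):
        obs = toy_obs()
        grid = compute_posterior(obs, np.array([1.0]), np.array([0.5]))
        assert grid.mass.shape == (1, 1)
        assert grid.mass[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_masses_normalised(self, smooth_obs):
        grid = compute_posterior(
            smooth_obs, np.geomspace(0.2, 30, 12), np.linspace(0, 2, 8)
        )
        assert grid.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_of_correlation_marginals(self, smooth_obs):
        phi_g, tau_g = np.geomspace(0.2, 30, 8), np.linspace(0, 2, 6)
        g1 = compute_posterior(smooth_obs, phi_g, tau_g)
        scaled = SpatialObservations(
            smooth_obs.coords, 37.5 * smooth_obs.y, trend=smooth_obs.trend
        )
        g2 = compute_posterior(scaled, phi_g, tau_g)
        assert np.allclose(g1.mass, g2.mass, atol=1e-10)
        # sigma2 statistics scale by c^2
        assert np.allclose(g2.s2, 37.5**2 * g1.s2)

    def test_pure_nugget_data_concentrates_nugget_ratio_near_one(self, design):
        truth = SimulationTruth(
            beta=(10.0, 0.0, 0.0), sigma2=0.01, phi=0.5, tau2_rel=400.0
        )
        obs = simulate_field(design, truth, seed=21)
        model = BayesianKriging(
            n_phi=20, n_tau=20, tau2rel_max=1000.0, n_draws=4000, random_state=0
        ).fit(obs.coords, obs.y)
        assert model.summary_.loc["nugget_ratio", "mean"] > 0.9

    def test_phi_recovery_within_factor_two_most_of_the_time(self, design):
        truth = SimulationTruth(beta=(0.0, 0.0, 0.0), sigma2=1.0, phi=3.0, tau2_rel=0.1)
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            obs = simulate_field(design, truth, seed=5000 + rep)
            grid = compute_posterior(
                obs, np.geomspace(34 / 300, 34, 25), np.linspace(0, 4, 25)
            )
            phi_mode = grid.mode[0]
            hits += 1.5 <= phi_mode <= 6.0
        assert hits >= 0.8 * n_reps


@pytest.fixture(scope="module")
def fitted_grid(smooth_obs):
    return compute_posterior(
        smooth_obs, np.geomspace(0.3, 30, 10), np.linspace(0, 2, 8)
    )


class TestSampling:
    def test_single_cell_grid_all_draws_identical(self, smooth_obs):
        grid = compute_posterior(smooth_obs, np.array([2.0]), np.array([0.3]))
        draws = sample_posterior(grid, 500, random_state=0)
        assert np.all(draws.phi == 2.0)
        assert np.all(draws.tau2rel == 0.3)

    def test_cell_frequencies_match_masses(self, fitted_grid):
        n = 100_000
        draws = sample_posterior(fitted_grid, n, random_state=1)
        mass = fitted_grid.mass.ravel()
        freq = np.bincount(draws.cell, minlength=mass.size) / n
        se = np.sqrt(mass * (1 - mass) / n)
        # binomial check on cells with enough expected draws for normality
        big = mass * n >= 50
        assert big.any()
        assert np.all(np.abs(freq[big] - mass[big]) <= 3.5 * se[big])
        # negligible-mass cells collectively stay negligible
        assert freq[~big].sum() <= mass[~big].sum() + 3.5 * np.sqrt(mass[~big].sum() / n) + 1e-9

    def test_sigma2_mean_matches_analytic(self, fitted_grid):
        draws = sample_posterior(fitted_grid, 200_000, random_state=2)
        analytic = float(
            np.nansum(fitted_grid.mass * fitted_grid.s2 / (fitted_grid.df - 2))
        )
        assert draws.sigma2.mean() == pytest.approx(analytic, rel=0.02)
        assert np.all(draws.sigma2 > 0)

    def test_invalid_draw_count_rejected(self, fitted_grid):
        with pytest.raises(ValueError):
            sample_posterior(fitted_grid, 0)


class TestPrediction:
    def test_conditional_krige_matches_hand_linear_algebra(self):
        obs = SpatialObservations(
            coords=np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]),
            y=np.array([1.0, 2.0, 0.5]),
            trend="constant",
        )
        phi, tau, s2, beta = 1.5, 0.3, 2.0, np.array([0.5])
        t = np.array([[1.7, 0.0]])
        mu, var = conditional_krige(obs, t, beta, s2, phi, tau)
        v = np.exp(-cdist(obs.coords, obs.coords) / phi) + tau * np.eye(3)
        r = np.exp(-cdist(t, obs.coords) / phi)
        mu_hand = beta[0] + r @ np.linalg.solve(v, obs.y - beta[0])
        var_hand = s2 * (1 - r @ np.linalg.solve(v, r.T))
        assert abs(mu[0] - mu_hand[0]) < 1e-10
        assert abs(var[0] - var_hand[0, 0]) < 1e-10

    def test_exact_interpolation_without_nugget(self, smooth_obs):
        model = BayesianKriging(
            n_phi=12, tau2rel_grid=np.array([0.0]), n_draws=2000, random_state=0
        ).fit(smooth_obs.coords, smooth_obs.y)
        pred, sd = model.predict(smooth_obs.coords, return_std=True)
        assert np.max(np.abs(pred - smooth_obs.y)) < 1e-8
        assert np.max(sd) < 1e-3

    def test_far_target_reverts_to_gls_trend(self, design):
        truth = SimulationTruth(beta=(5.0, 0.2, -0.1), sigma2=1.0, phi=2.0, tau2_rel=0.3)
        obs = simulate_field(design, truth, seed=5)
        model = BayesianKriging(
            phi_grid=np.array([2.0]),
            tau2rel_grid=np.array([0.3]),
            n_draws=200_000,
            random_state=1,
        ).fit(obs.coords, obs.y)
        far = np.array([[200.0, 200.0]])  # ~100 correlation scales away
        with pytest.warns(UserWarning, match="outside"):
            pred = model.predict(far)
        gls = np.array([1.0, 200.0, 200.0]) @ model.posterior_.beta_hat[0, 0]
        assert pred[0] == pytest.approx(gls, rel=5e-3)

    def test_surface_shape_and_columns(self, smooth_obs):
        model = BayesianKriging(n_phi=8, n_tau=8, n_draws=1000, random_state=0).fit(
            smooth_obs.coords, smooth_obs.y
        )
        surf = model.predict_surface(spacing=4.0)
        assert set(surf.columns) == {"x_m", "y_m", "pred_mean", "pred_sd"}
        assert (surf["pred_sd"] >= 0).all()
        assert len(surf) == 9 * 5  # 34x16 box at 4 m spacing


class TestSummaries:
    def _draws(self, phi, tau, sigma2, beta0):
        n = len(phi)
        return PosteriorDraws(
            phi=np.asarray(phi, float),
            tau2rel=np.asarray(tau, float),
            sigma2=np.asarray(sigma2, float),
            beta=np.asarray(beta0, float)[:, None],
            cell=np.zeros(n, dtype=np.intp),
        )

    def test_identical_draws_collapse_to_point(self):
        d = self._draws([2.0] * 10, [0.5] * 10, [1.2] * 10, [7.0] * 10)
        s = summarize_draws(d)
        assert np.allclose(s["mean"], s["q5"])
        assert np.allclose(s["mean"], s["q95"])
        assert s.loc["range_m", "mean"] == pytest.approx(6.0)
        assert s.loc["nugget_ratio", "mean"] == pytest.approx(0.5 / 1.5)

    def test_uniform_phi_draws_mean_range(self):
        d = self._draws([1.0, 2.0, 3.0] * 100, [0.0] * 300, [1.0] * 300, [0.0] * 300)
        assert summarize_draws(d).loc["range_m", "mean"] == pytest.approx(6.0)

    def test_nugget_ratio_is_mean_of_per_draw_ratios(self):
        # bimodal set where the ratio of summary means would differ
        d = self._draws(
            [1.0, 1.0], [0.0, 9.0], [1.0, 1.0], [0.0, 0.0]
        )
        s = summarize_draws(d)
        per_draw = np.array([0.0, 0.9])
        assert s.loc["nugget_ratio", "mean"] == pytest.approx(per_draw.mean())
        ratio_of_means = (0.0 + 9.0) / 2 / ((0.0 + 9.0) / 2 + 1.0)
        assert s.loc["nugget_ratio", "mean"] != pytest.approx(ratio_of_means)


class TestLOO:
    def test_attains_exact_parameter_oracle_on_smooth_field(self, design):
        truth = SimulationTruth(beta=(5.0, 0.0, 0.0), sigma2=1.0, phi=100.0, tau2_rel=0.0)
        obs = simulate_field(design, truth, seed=3)
        _, adj_r2 = loo_cross_validate(obs, n_phi=20, n_tau=20)
        # oracle: LOO prediction with the true parameters
        n = obs.n
        oracle_pred = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            sub = SpatialObservations(obs.coords[keep], obs.y[keep], trend="constant")
            mu, _ = conditional_krige(sub, obs.coords[[i]], [5.0], 1.0, 100.0, 0.0)
            oracle_pred[i] = mu[0]
        r2_oracle = np.corrcoef(obs.y, oracle_pred)[0, 1] ** 2
        adj_oracle = 1 - (1 - r2_oracle) * (n - 1) / (n - 3 - 1)
        assert adj_r2 > 0.95
        assert abs(adj_r2 - adj_oracle) < 0.02

    def test_pure_noise_r2_near_zero(self, design):
        truth = SimulationTruth(beta=(5.0, 0.0, 0.0), sigma2=1e-6, phi=2.0, tau2_rel=1e6)
        obs = simulate_field(design, truth, seed=4)
        _, adj_r2 = loo_cross_validate(obs, n_phi=10, n_tau=10)
        assert abs(adj_r2) < 0.2

    def test_invariant_to_observation_ordering(self):
        from firekrige import generate_design

        small = generate_design(spacings=(2.0, 2.0, 4.0, 8.0), n_rows=3)
        truth = SimulationTruth(beta=(1.0, 0.1, 0.0), sigma2=1.0, phi=3.0, tau2_rel=0.2)
        obs = simulate_field(small, truth, seed=6)
        table, r2 = loo_cross_validate(obs, n_phi=8, n_tau=8)
        perm = np.random.default_rng(0).permutation(obs.n)
        obs_p = SpatialObservations(obs.coords[perm], obs.y[perm], trend=obs.trend)
        table_p, r2_p = loo_cross_validate(obs_p, n_phi=8, n_tau=8)
        assert r2 == pytest.approx(r2_p, abs=1e-9)
        assert np.allclose(
            table["predicted"].to_numpy()[perm], table_p["predicted"].to_numpy()
        )


class TestValidation:
    def test_duplicate_locations_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SpatialObservations(
                coords=np.array([[0, 0], [0, 0], [1, 1], [2, 2], [3, 3]], float),
                y=np.zeros(5),
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            SpatialObservations(coords=np.array([[0.0, 0], [1, 0]]), y=np.zeros(2))

    def test_estimator_is_sklearn_compatible(self, smooth_obs):
        from sklearn.base import clone

        m = BayesianKriging(n_phi=5, n_tau=5, n_draws=100, random_state=0)
        m2 = clone(m)
        assert m2.get_params()["n_phi"] == 5
        m2.set_params(n_draws=200).fit(smooth_obs.coords, smooth_obs.y)
        assert m2.draws_.n_draws == 200
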