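"""Bayesian model-based geostatistics with a discrete correlation-parameter posterior.

The spatial model is a three-level Gaussian hierarchy

    Y(u) = X(u) beta + S(u) + eps(u)

where ``S`` is a zero-mean stationary Gaussian process with partial sill
``sigma2`` and exponential correlation ``R(h; phi) = exp(-h/phi)`` (the range
of spatial autocorrelation is conventionally ``3 * phi``, where correlation
drops to ~0.05), and ``eps`` is independent measurement noise ("nugget") with
variance ``sigma2 * tau2rel``.  Priors are flat on ``beta``, reciprocal
(``1/sigma2``) on ``sigma2``, and uniform over a predefined discrete grid of
``(phi, tau2rel)`` pairs.  Conditional on a grid cell, ``(beta, sigma2)`` are
conjugate: ``sigma2`` is scaled inverse-chi-squared and ``beta | sigma2`` is
Gaussian, so the cell posterior mass has the closed form

    p(phi, tau2rel | y)  ∝  |V|^(-1/2) |X'V^-1 X|^(-1/2) (S2)^(-(n-p)/2)

with ``V = R(phi) + tau2rel * I``, ``beta_hat`` the GLS estimate and ``S2``
the generalised residual sum of squares.  Posterior draws, kriging prediction
and leave-one-out validation all flow from these per-cell statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

__all__ = [
    "exp_correlation",
    "SpatialObservations",
    "PosteriorGrid",
    "PosteriorDraws",
    "log_marginal",
    "compute_posterior",
    "sample_posterior",
    "conditional_krige",
    "summarize_draws",
    "BayesianKriging",
    "loo_cross_validate",
]

# Eigenvalues of the correlation matrix are clipped here before inversion; a
# warning is emitted when clipping actually fires (numerically degenerate phi).
_EIG_FLOOR = 1e-12


def exp_correlation(h: ArrayLike, phi: float) -> NDArray[np.float64]:
    """Exponential correlation function ``exp(-h / phi)``.

    Parameters
    ----------
    h : array-like
        Non-negative lag distance(s), metres.
    phi : float
        Correlation scale parameter, metres; the nominal range (correlation
        ~0.05) is ``3 * phi``.
    """
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("lag distances must be non-negative")
    return np.exp(-h / phi)


def trend_matrix(coords: NDArray, trend: str = "linear") -> NDArray[np.float64]:
    """Design matrix for the spatial trend: ``linear`` is intercept + x + y,
    ``constant`` is intercept only."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if trend == "constant":
        return np.ones((n, 1))
    if trend == "linear":
        return np.column_stack([np.ones(n), coords])
    raise ValueError(f"unknown trend {trend!r}; use 'linear' or 'constant'")


@dataclass
class SpatialObservations:
    """Point-referenced observations of one response variable.

    Attributes
    ----------
    coords : (n, 2) array
        Planar coordinates in metres, origin at the plot corner.
    y : (n,) array
        Response values (units of the variable under study).
    trend : str
        ``"linear"`` (intercept + x + y) or ``"constant"``.
    core_id : optional sequence of identifiers, carried through I/O.
    """

    coords: NDArray[np.float64]
    y: NDArray[np.float64]
    trend: str = "linear"
    core_id: list | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2 (x_m, y_m)")
        if self.coords.shape[0] != self.y.size:
            raise ValueError("coords and y length mismatch")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("missing or non-finite responses are not allowed")
        n, p = self.y.size, self.X.shape[1]
        if n < p + 2:
            raise ValueError(f"need at least p + 2 = {p + 2} observations, got {n}")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("duplicate observation locations")

    @property
    def X(self) -> NDArray[np.float64]:
        return trend_matrix(self.coords, self.trend)

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class PosteriorGrid:
    """Discrete joint posterior over (phi, tau2rel) with cached conjugate
    statistics for (beta, sigma2) in every cell."""

    phi: NDArray[np.float64]          # (n_phi,)
    tau2rel: NDArray[np.float64]      # (n_tau,)
    log_mass: NDArray[np.float64]     # (n_phi, n_tau), normalised in log space
    beta_hat: NDArray[np.float64]     # (n_phi, n_tau, p) GLS estimates
    beta_cov_chol: NDArray[np.float64]  # (n_phi, n_tau, p, p), chol of (X'V^-1X)^-1
    s2: NDArray[np.float64]           # (n_phi, n_tau) generalised RSS
    df: int                           # n - p
    n_degenerate: int = 0

    @property
    def mass(self) -> NDArray[np.float64]:
        return np.exp(self.log_mass)

    @property
    def mode(self) -> tuple[float, float]:
        """(phi, tau2rel) of the highest-mass cell; ties broken toward the
        smallest phi."""
        m = self.mass
        best = np.flatnonzero(m.ravel() == m.max())
        i, j = np.unravel_index(best[0], m.shape)  # row-major: smallest phi first
        return float(self.phi[i]), float(self.tau2rel[j])

    def mode_on_edge(self) -> bool:
        i = int(np.searchsorted(self.phi, self.mode[0]))
        return i in (0, self.phi.size - 1)


@dataclass
class PosteriorDraws:
    """Monte-Carlo draws of (beta, sigma2, phi, tau2rel); (phi, tau2rel) lie
    on the prior grid."""

    phi: NDArray[np.float64]
    tau2rel: NDArray[np.float64]
    sigma2: NDArray[np.float64]
    beta: NDArray[np.float64]     # (n_draws, p)
    cell: NDArray[np.intp]        # flat grid-cell index of each draw
    grid_shape: tuple[int, int] = field(default=(0, 0))

    @property
    def n_draws(self) -> int:
        return self.phi.size

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"phi": self.phi, "tau2rel": self.tau2rel, "sigma2": self.sigma2})
        for j in range(self.beta.shape[1]):
            out[f"beta{j}"] = self.beta[:, j]
        return out


def _eig_correlation(dists: NDArray, phi: float) -> tuple[NDArray, NDArray, bool]:
    """Eigendecomposition of R(phi); returns (eigenvalues, Q, clipped)."""
    r = np.exp(-dists / phi)
    lam, q = np.linalg.eigh(r)
    clipped = bool(lam[0] < _EIG_FLOOR)
    return np.maximum(lam, _EIG_FLOOR), q, clipped


def _cell_stats(lam, xq, yq, tau2rel):
    """Conjugate statistics for one grid cell given the spectral form of V.

    ``V = Q diag(lam + tau2rel) Q'``; xq, yq are X and y rotated by Q'.
    Returns (log unnormalised marginal, beta_hat, chol((X'V^-1X)^-1), S2)
    or None when the cell is numerically degenerate.
    """
    w = lam + tau2rel
    if np.any(w <= 0):
        return None
    inv_w = 1.0 / w
    xtvx = (xq * inv_w[:, None]).T @ xq
    xtvy = xq.T @ (inv_w * yq)
    try:
        lx = np.linalg.cholesky(xtvx)
    except np.linalg.LinAlgError:
        return None
    beta_hat = np.linalg.solve(xtvx, xtvy)
    s2 = float(yq @ (inv_w * yq) - beta_hat @ xtvy)
    if s2 <= 0:
        return None
    n, p = xq.shape
    logdet_v = float(np.sum(np.log(w)))
    logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(lx))))
    logm = -0.5 * logdet_v - 0.5 * logdet_xtvx - 0.5 * (n - p) * np.log(s2)
    # chol of (X'V^-1X)^-1 from the chol of X'V^-1X
    cov_chol = np.linalg.cholesky(np.linalg.inv(xtvx))
    return logm, beta_hat, cov_chol, s2


def log_marginal(
    obs: SpatialObservations, phi: float, tau2rel: float
) -> float:
    """Log marginal density of (phi, tau2rel) given the data, up to a constant
    shared across the grid (beta and sigma2 analytically integrated out)."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    if tau2rel < 0:
        raise ValueError("tau2rel must be non-negative")
    dists = cdist(obs.coords, obs.coords)
    lam, q, _ = _eig_correlation(dists, phi)
    out = _cell_stats(lam, q.T @ obs.X, q.T @ obs.y, tau2rel)
    if out is None:
        return -np.inf
    return out[0]


def compute_posterior(
    obs: SpatialObservations,
    phi_grid: ArrayLike,
    tau2rel_grid: ArrayLike,
) -> PosteriorGrid:
    """Discrete joint posterior of (phi, tau2rel) on the prior grid, with
    per-cell conjugate statistics cached for sampling and prediction.

    The prior is uniform over grid cells; masses are accumulated in log space
    and normalised after subtracting the maximum.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    tau_grid = np.asarray(tau2rel_grid, dtype=float)
    if phi_grid.ndim != 1 or np.any(np.diff(phi_grid) <= 0) or phi_grid[0] <= 0:
        raise ValueError("phi_grid must be strictly increasing and positive")
    if tau_grid.ndim != 1 or np.any(np.diff(tau_grid) <= 0) or tau_grid[0] < 0:
        raise ValueError("tau2rel_grid must be strictly increasing and >= 0")

    x, y = obs.X, obs.y
    n, p = x.shape
    dists = cdist(obs.coords, obs.coords)
    n_phi, n_tau = phi_grid.size, tau_grid.size

    logm = np.full((n_phi, n_tau), -np.inf)
    beta_hat = np.zeros((n_phi, n_tau, p))
    cov_chol = np.zeros((n_phi, n_tau, p, p))
    s2 = np.full((n_phi, n_tau), np.nan)
    n_bad = 0
    any_clip = False
    for i, phi in enumerate(phi_grid):
        lam, q, clipped = _eig_correlation(dists, phi)
        any_clip = any_clip or clipped
        xq, yq = q.T @ x, q.T @ y
        for j, tau in enumerate(tau_grid):
            out = _cell_stats(lam, xq, yq, tau)
            if out is None:
                n_bad += 1
                continue
            logm[i, j], beta_hat[i, j], cov_chol[i, j], s2[i, j] = out
    if any_clip:
        warnings.warn(
            "correlation matrix required eigenvalue clipping for some phi "
            "(numerically degenerate correlation scale)", RuntimeWarning,
            stacklevel=2,
        )
    if n_bad:
        warnings.warn(
            f"{n_bad} grid cell(s) were numerically degenerate and received "
            "zero posterior mass", RuntimeWarning, stacklevel=2,
        )
    if not np.any(np.isfinite(logm)):
        raise ValueError("no admissible correlation parameters: every grid cell degenerate")
    top = logm.max()
    log_z = top + np.log(np.sum(np.exp(logm - top)))
    return PosteriorGrid(
        phi=phi_grid, tau2rel=tau_grid, log_mass=logm - log_z,
        beta_hat=beta_hat, beta_cov_chol=cov_chol, s2=s2, df=n - p,
        n_degenerate=n_bad,
    )


def sample_posterior(
    grid: PosteriorGrid, n_draws: int = 100_000, random_state=None
) -> PosteriorDraws:
    """Draw from the joint posterior: grid cells by their masses, then
    ``sigma2`` from its scaled inverse-chi-squared conditional and ``beta``
    from its Gaussian conditional given ``sigma2``."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = check_random_state(random_state)
    n_phi, n_tau = grid.log_mass.shape
    p = grid.beta_hat.shape[-1]
    mass = grid.mass.ravel()
    cells = rng.choice(mass.size, size=n_draws, p=mass / mass.sum())

    phi = grid.phi[cells // n_tau]
    tau = grid.tau2rel[cells % n_tau]
    sigma2 = np.empty(n_draws)
    beta = np.empty((n_draws, p))
    for c in np.unique(cells):
        idx = np.flatnonzero(cells == c)
        i, j = divmod(int(c), n_tau)
        # sigma2 | cell ~ S2 / chi2_df  (scaled inverse-chi-squared)
        sigma2[idx] = grid.s2[i, j] / rng.chisquare(grid.df, size=idx.size)
        z = rng.standard_normal((idx.size, p))
        beta[idx] = grid.beta_hat[i, j] + np.sqrt(sigma2[idx])[:, None] * (
            z @ grid.beta_cov_chol[i, j].T
        )
    return PosteriorDraws(
        phi=phi, tau2rel=tau, sigma2=sigma2, beta=beta, cell=cells,
        grid_shape=(n_phi, n_tau),
    )


def conditional_krige(
    obs: SpatialObservations,
    targets: ArrayLike,
    beta: ArrayLike,
    sigma2: float,
    phi: float,
    tau2rel: float,
) -> tuple[NDArray, NDArray]:
    """Conditional mean and variance of the signal ``X beta + S`` at target
    locations, given the observations and *fixed* model parameters.

    These are the simple-kriging equations: with ``r`` the target-observation
    correlation vector and ``V = R + tau2rel I``,

        mean = x_t' beta + r' V^-1 (y - X beta)
        var  = sigma2 * (1 - r' V^-1 r)

    The nugget is excluded from the predicted quantity (the signal, not a
    noisy re-measurement).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    beta = np.asarray(beta, dtype=float).ravel()
    v = exp_correlation(cdist(obs.coords, obs.coords), phi) + tau2rel * np.eye(obs.n)
    r = exp_correlation(cdist(targets, obs.coords), phi)  # (n_t, n)
    w = np.linalg.solve(v, r.T).T                          # r' V^-1, (n_t, n)
    xt = trend_matrix(targets, obs.trend)
    mean = xt @ beta + w @ (obs.y - obs.X @ beta)
    var = sigma2 * np.clip(1.0 - np.sum(w * r, axis=1), 0.0, None)
    return mean, var


def _predict_from_draws(obs, grid, draws, targets):
    """Across-draw predictive mean and variance at target locations.

    Draws sharing a grid cell share all V-dependent linear algebra, so the
    per-cell work is one factorisation plus moment accumulation; the cost is
    independent of the number of draws per cell.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    nt = targets.shape[0]
    x, y = obs.X, obs.y
    xt = trend_matrix(targets, obs.trend)
    dists = cdist(obs.coords, obs.coords)
    rt = cdist(targets, obs.coords)
    n_tau = grid.tau2rel.size

    total = draws.n_draws
    sum_mean = np.zeros(nt)
    sum_mean2 = np.zeros(nt)
    sum_cvar = np.zeros(nt)
    for c in np.unique(draws.cell):
        idx = np.flatnonzero(draws.cell == c)
        i, j = divmod(int(c), n_tau)
        phi, tau = grid.phi[i], grid.tau2rel[j]
        v = np.exp(-dists / phi) + tau * np.eye(obs.n)
        r = np.exp(-rt / phi)
        w = np.linalg.solve(v, r.T).T
        wy = w @ y
        m = xt - w @ x                      # (nt, p): trend part of the mean
        svar = np.clip(1.0 - np.sum(w * r, axis=1), 0.0, None)

        b = draws.beta[idx]                 # (k, p)
        k = idx.size
        sum_b = b.sum(axis=0)
        sum_bbt = b.T @ b
        # per-draw mean_d = wy + m @ beta_d; accumulate sum and sum of squares
        sum_mean += k * wy + m @ sum_b
        sum_mean2 += k * wy**2 + 2.0 * wy * (m @ sum_b) + np.einsum(
            "tp,pq,tq->t", m, sum_bbt, m
        )
        sum_cvar += draws.sigma2[idx].sum() * svar
    mean = sum_mean / total
    var = sum_cvar / total + np.clip(sum_mean2 / total - mean**2, 0.0, None)
    return mean, var


def summarize_draws(draws: PosteriorDraws, level: float = 0.90) -> pd.DataFrame:
    """Posterior summary table: mean and central credible bounds of the trend
    intercept, range (= 3 phi, m), sill sigma2, nugget tau2rel*sigma2 and the
    nugget ratio nugget/(nugget + sill), each computed per draw first."""
    if draws.n_draws < 1:
        raise ValueError("no draws to summarise")
    lo, hi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    nugget = draws.tau2rel * draws.sigma2
    rows = {
        "trend": draws.beta[:, 0],
        "range_m": 3.0 * draws.phi,
        "sill": draws.sigma2,
        "nugget": nugget,
        "nugget_ratio": nugget / (nugget + draws.sigma2),
    }
    table = pd.DataFrame(
        {
            "mean": {k: np.mean(v) for k, v in rows.items()},
            f"q{lo * 100:.0f}": {k: np.quantile(v, lo) for k, v in rows.items()},
            f"q{hi * 100:.0f}": {k: np.quantile(v, hi) for k, v in rows.items()},
        }
    )
    table.index.name = "parameter"
    return table


def default_phi_grid(coords: NDArray, n_phi: int = 100, bounds=None) -> NDArray:
    """Log-spaced phi grid; default bounds span sub-grain to whole-plot scales
    (largest coordinate span / 300 up to the span itself)."""
    if bounds is None:
        span = float(np.ptp(np.asarray(coords, dtype=float), axis=0).max())
        if span <= 0:
            raise ValueError("degenerate coordinates: zero spatial span")
        bounds = (span / 300.0, span)
    lo, hi = bounds
    if not 0 < lo < hi:
        raise ValueError("phi bounds must satisfy 0 < lo < hi")
    return np.geomspace(lo, hi, n_phi)


def default_tau2rel_grid(n_tau: int = 100, tau_max: float = 4.0) -> NDArray:
    """Linear relative-nugget grid on [0, tau_max], 0 included."""
    return np.linspace(0.0, tau_max, n_tau)


class BayesianKriging(RegressorMixin, BaseEstimator):
    """Bayesian kriging of a spatial variable on a plot.

    Fits the Gaussian spatial linear model with exponential correlation by
    exact conjugate analysis on a discrete ``(phi, tau2rel)`` grid, draws from
    the joint posterior, and predicts the underlying signal at new locations
    from the posterior predictive distribution.

    Parameters
    ----------
    phi_grid, tau2rel_grid : arrays, optional
        Explicit prior grids.  When omitted, ``n_phi`` log-spaced phi values
        over ``phi_bounds`` (default: largest coordinate span / 300 up to the
        span) and ``n_tau`` linear tau2rel values on [0, tau2rel_max].
    trend : {"linear", "constant"}
        Spatial trend: intercept + x + y, or intercept only.
    n_draws : int
        Posterior sample size drawn at fit time (default 100,000).
    random_state : int, RandomState or None
        Seed for posterior sampling.

    Attributes
    ----------
    obs_ : SpatialObservations
    posterior_ : PosteriorGrid
    draws_ : PosteriorDraws
    summary_ : DataFrame with mean / 5% / 95% of trend, range_m, sill,
        nugget and nugget_ratio.

    Examples
    --------
    >>> import numpy as np
    >>> from firekrige import BayesianKriging
    >>> rng = np.random.default_rng(0)
    >>> coords = rng.uniform(0, 10, size=(40, 2))
    >>> y = coords @ [0.3, -0.2] + rng.normal(size=40)
    >>> model = BayesianKriging(n_phi=15, n_tau=15, n_draws=2000,
    ...                         random_state=0).fit(coords, y)
    >>> model.summary_.loc["range_m", "mean"] > 0
    True
    """

    def __init__(
        self,
        phi_grid=None,
        tau2rel_grid=None,
        n_phi: int = 100,
        n_tau: int = 100,
        phi_bounds=None,
        tau2rel_max: float = 4.0,
        trend: str = "linear",
        n_draws: int = 100_000,
        random_state=None,
    ):
        self.phi_grid = phi_grid
        self.tau2rel_grid = tau2rel_grid
        self.n_phi = n_phi
        self.n_tau = n_tau
        self.phi_bounds = phi_bounds
        self.tau2rel_max = tau2rel_max
        self.trend = trend
        self.n_draws = n_draws
        self.random_state = random_state

    def _grids(self, coords):
        phi = (
            np.asarray(self.phi_grid, dtype=float)
            if self.phi_grid is not None
            else default_phi_grid(coords, self.n_phi, self.phi_bounds)
        )
        tau = (
            np.asarray(self.tau2rel_grid, dtype=float)
            if self.tau2rel_grid is not None
            else default_tau2rel_grid(self.n_tau, self.tau2rel_max)
        )
        return phi, tau

    def fit(self, X, y):
        """Fit to coordinates ``X`` (n x 2, metres) and responses ``y``."""
        X = check_array(X)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] != 2:
            raise ValueError("X must have two columns (x_m, y_m)")
        self.obs_ = SpatialObservations(coords=X, y=y, trend=self.trend)
        phi_grid, tau_grid = self._grids(X)
        self.posterior_ = compute_posterior(self.obs_, phi_grid, tau_grid)
        self.draws_ = sample_posterior(
            self.posterior_, self.n_draws, self.random_state
        )
        self.summary_ = summarize_draws(self.draws_)
        self.n_features_in_ = 2
        return self

    def predict(self, X, return_std: bool = False):
        """Posterior predictive mean (and optionally sd) of the signal at the
        given locations; warns for locations outside the observed bounding
        box rather than failing."""
        check_is_fitted(self, "posterior_")
        X = check_array(X)
        lo = self.obs_.coords.min(axis=0)
        hi = self.obs_.coords.max(axis=0)
        if np.any(X < lo) or np.any(X > hi):
            warnings.warn(
                "some prediction locations fall outside the observed bounding "
                "box; extrapolating", UserWarning, stacklevel=2,
            )
        mean, var = _predict_from_draws(self.obs_, self.posterior_, self.draws_, X)
        if return_std:
            return mean, np.sqrt(var)
        return mean

    def predict_surface(self, spacing: float = 0.5) -> pd.DataFrame:
        """Kriged map on a regular grid over the observed bounding box
        (default 0.5 m spacing); columns x_m, y_m, pred_mean, pred_sd."""
        check_is_fitted(self, "posterior_")
        lo = self.obs_.coords.min(axis=0)
        hi = self.obs_.coords.max(axis=0)
        xs = np.arange(lo[0], hi[0] + spacing / 2, spacing)
        ys = np.arange(lo[1], hi[1] + spacing / 2, spacing)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        mean, sd = self.predict(pts, return_std=True)
        return pd.DataFrame(
            {"x_m": pts[:, 0], "y_m": pts[:, 1], "pred_mean": mean, "pred_sd": sd}
        )


def _mixture_predictive(obs, grid, targets):
    """Exact posterior predictive mean/variance at targets, mixing the
    closed-form per-cell conditionals by the grid masses (no Monte Carlo).

    Per cell the signal predictive given (phi, tau2rel) is Student-like:
    mean uses beta_hat, variance is E[sigma2|cell] * (kriging variance +
    trend-uncertainty term), with E[sigma2|cell] = S2 / (df - 2).
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    x, y = obs.X, obs.y
    xt = trend_matrix(targets, obs.trend)
    dists = cdist(obs.coords, obs.coords)
    rt = cdist(targets, obs.coords)
    mass = grid.mass
    if grid.df <= 2:
        raise ValueError("need df > 2 for a finite predictive variance")

    mean_acc = np.zeros(targets.shape[0])
    m2_acc = np.zeros(targets.shape[0])
    var_acc = np.zeros(targets.shape[0])
    for i, phi in enumerate(grid.phi):
        col = mass[i]
        if col.max() < 1e-14:  # negligible slice, skip the factorisation
            continue
        for j, tau in enumerate(grid.tau2rel):
            w_cell = col[j]
            if w_cell < 1e-16 or not np.isfinite(grid.s2[i, j]):
                continue
            v = np.exp(-dists / phi) + tau * np.eye(obs.n)
            r = np.exp(-rt / phi)
            wmat = np.linalg.solve(v, r.T).T
            beta_hat = grid.beta_hat[i, j]
            mu = xt @ beta_hat + wmat @ (y - x @ beta_hat)
            svar = np.clip(1.0 - np.sum(wmat * r, axis=1), 0.0, None)
            m = xt - wmat @ x
            l_beta = grid.beta_cov_chol[i, j]
            trend_var = np.sum((m @ l_beta) ** 2, axis=1)
            e_sig2 = grid.s2[i, j] / (grid.df - 2)
            mean_acc += w_cell * mu
            m2_acc += w_cell * mu**2
            var_acc += w_cell * e_sig2 * (svar + trend_var)
    mean = mean_acc
    var = var_acc + np.clip(m2_acc - mean**2, 0.0, None)
    return mean, var


def loo_cross_validate(
    obs: SpatialObservations,
    phi_grid=None,
    tau2rel_grid=None,
    n_phi: int = 25,
    n_tau: int = 25,
    seed=None,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation of the spatial model.

    Each observation is predicted from the remaining n - 1 with the full
    posterior refit on a reduced grid (default 25 x 25).  Returns a per-point
    table (observed, predicted, predictive variance) and the adjusted R²:
    R² is the squared Pearson correlation of observed vs predicted, adjusted
    as ``1 - (1 - R²)(n - 1)/(n - p - 1)``.  The predictive moments are exact
    grid mixtures, so the result is deterministic; ``seed`` is accepted for
    interface stability and unused.
    """
    n = obs.n
    p = obs.X.shape[1]
    if n < p + 3:
        raise ValueError(f"need at least p + 3 = {p + 3} points for LOO")
    if phi_grid is None:
        phi_grid = default_phi_grid(obs.coords, n_phi)
    if tau2rel_grid is None:
        tau2rel_grid = default_tau2rel_grid(n_tau)

    pred = np.full(n, np.nan)
    pvar = np.full(n, np.nan)
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        keep = np.arange(n) != i
        sub = SpatialObservations(
            coords=obs.coords[keep], y=obs.y[keep], trend=obs.trend
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                grid = compute_posterior(sub, phi_grid, tau2rel_grid)
            mu, var = _mixture_predictive(sub, grid, obs.coords[[i]])
        except (ValueError, np.linalg.LinAlgError):
            ok[i] = False
            continue
        pred[i], pvar[i] = mu[0], var[0]
    if not np.all(ok):
        warnings.warn(
            f"{np.sum(~ok)} left-out point(s) had a degenerate refit and were "
            "excluded from the cross-validation R²", RuntimeWarning, stacklevel=2,
        )
    table = pd.DataFrame(
        {"observed": obs.y, "predicted": pred, "pred_var": pvar, "ok": ok}
    )
    use = ok & np.isfinite(pred)
    n_eff = int(use.sum())
    r = np.corrcoef(obs.y[use], pred[use])[0, 1]
    r2 = r**2
    adj_r2 = 1.0 - (1.0 - r2) * (n_eff - 1) / (n_eff - p - 1)
    return table, float(adj_r2)
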