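"""Discrete-prior hierarchical Bayesian kriging.

Model
-----
Observations ``Y_i`` at locations ``x_i`` are conditionally independent given
a stationary Gaussian process ``S``:

    Y_i = f(x_i)' beta + S(x_i) + eps_i,      eps_i ~ N(0, tau2) iid
    S    ~ GP(0, sigma2 * exp(-h / phi))

with a constant trend (f = 1), flat priors on beta and on the discretized
``(phi, nu)`` pair (``nu = tau2 / sigma2`` is the relative nugget) and a
reciprocal (scale-invariant) prior on ``sigma2``.  Writing
``V = R(phi) + nu * I`` (correlation scale), the marginals of ``beta`` and
``sigma2`` are available in closed form, leaving a discrete posterior over
the ``(phi, nu)`` grid:

    p(phi, nu | y)  ∝  pi(phi, nu) |V|^(-1/2) |F'V^(-1)F|^(-1/2) (S^2)^(-(n-p)/2)

where ``beta_hat`` is the GLS mean and ``S^2`` the GLS residual sum of
squares.  Conditionally, ``sigma2 | phi, nu, y`` is scaled-inverse-chi-square
with ``df = n - p`` and scale ``S^2 / df``, and
``beta | sigma2, phi, nu, y ~ N(beta_hat, sigma2 (F'V^(-1)F)^(-1))``.

Posterior draws propagate the full parameter uncertainty into the kriging
predictive distribution: per draw the conditional mean and variance at a
target are

    m0  = f0' beta + r0' V^(-1) (y - F beta)
    v0  = sigma2 * (c0 - r0' V^(-1) r0)

with ``c0 = 1`` for the noise-free signal and ``1 + nu`` for a new
observation; the map mean/variance combine draws by the law of total
variance.

An optional explicit sigma2 grid axis (``ParameterGrid(sigma2_values=...)``)
replaces the analytic conditional by a discretized one, for fidelity
experiments against fully gridded implementations.

Numerics: each phi's correlation matrix is eigendecomposed once, making the
nu axis (and any sigma2 axis) nearly free; all posterior arithmetic is in
the log domain with log-sum-exp normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

from .errors import (
    DegenerateDataError,
    FittingFailedError,
    InvalidInputError,
    InvalidParameterError,
    StateError,
)
from .geostat import VariogramParams, pairwise_distances
from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationSet",
    "ParameterGrid",
    "DiscretePosterior",
    "PredictiveMap",
    "PosteriorSummary",
    "log_marginal_posterior",
    "fit_discrete_posterior",
    "draw_posterior_samples",
    "krige_predict",
    "predict_fixed_params",
    "parameter_summaries",
]

_EIG_FLOOR = 1e-12  # floor on correlation-matrix eigenvalues
_S2_FLOOR = 1e-290  # keeps log S^2 finite for degenerate (constant) data
_DEFAULT_NDRAWS = 100_000


# ---------------------------------------------------------------------------
# data containers


@dataclass
class ObservationSet:
    """Georeferenced point observations of one variable on one date."""

    coords: np.ndarray  # (n, 2) meters
    values: np.ndarray  # (n,) variable units
    site_ids: np.ndarray | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.shape[0] == 0:
            raise InvalidInputError("observation set is empty")
        if self.coords.shape[1] != 2:
            raise InvalidInputError("coords must be (n, 2)")
        if self.values.shape != (self.coords.shape[0],):
            raise InvalidInputError("values length must match coords")
        if not np.isfinite(self.coords).all():
            raise InvalidInputError("coordinates must be finite")
        if not np.isfinite(self.values).all():
            raise InvalidInputError("values must be finite")
        if self.site_ids is None:
            self.site_ids = np.arange(self.coords.shape[0])
        else:
            self.site_ids = np.asarray(self.site_ids)
            if self.site_ids.shape[0] != self.coords.shape[0]:
                raise InvalidInputError("site_ids length must match coords")
        self._merge_duplicates()

    def _merge_duplicates(self) -> None:
        _, inverse, counts = np.unique(
            self.coords.round(9), axis=0, return_inverse=True, return_counts=True
        )
        if (counts > 1).any():
            n_dup = int((counts > 1).sum())
            logger.warning("merging %d duplicated coordinate group(s) by mean", n_dup)
            first = np.full(counts.size, len(inverse), dtype=int)
            np.minimum.at(first, inverse, np.arange(len(inverse)))
            sums = np.zeros(counts.size)
            np.add.at(sums, inverse, self.values)
            order = np.argsort(first)  # keep original row order
            self.values = (sums / counts)[order]
            self.coords = self.coords[first[order]]
            self.site_ids = self.site_ids[first[order]]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def drop(self, index: int) -> "ObservationSet":
        """Copy without observation ``index`` (for leave-one-out folds)."""
        keep = np.ones(self.n, dtype=bool)
        keep[index] = False
        return ObservationSet(
            coords=self.coords[keep],
            values=self.values[keep],
            site_ids=self.site_ids[keep],
            date=self.date,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, date: str | None = None) -> "ObservationSet":
        for col in ("x", "y", "value"):
            if col not in df.columns:
                raise InvalidInputError(f"missing mandatory column {col!r}")
        ids = df["site_id"].to_numpy() if "site_id" in df.columns else None
        return cls(
            coords=df[["x", "y"]].to_numpy(float),
            values=df["value"].to_numpy(float),
            site_ids=ids,
            date=date,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "value": self.values,
            }
        )


@dataclass
class ParameterGrid:
    """Discrete prior grid over (phi, nu) and optionally sigma2.

    Defaults follow the package convention: 100 linearly spaced phi values
    spanning (smallest nonzero pairwise distance, maximum pairwise distance)
    of the data — built lazily by :func:`default_grid` — and 100 linearly
    spaced nu values on [0, 2], with a flat prior.
    """

    phi_values: np.ndarray
    nu_values: np.ndarray
    prior_weights: np.ndarray | None = None  # (nphi, nnu), flat if None
    sigma2_values: np.ndarray | None = None  # optional explicit sigma2 axis

    def __post_init__(self) -> None:
        self.phi_values = np.asarray(self.phi_values, dtype=float)
        self.nu_values = np.asarray(self.nu_values, dtype=float)
        if self.phi_values.ndim != 1 or np.any(self.phi_values <= 0):
            raise InvalidParameterError("phi grid must be 1-D and positive")
        if np.any(np.diff(self.phi_values) <= 0) and self.phi_values.size > 1:
            raise InvalidParameterError("phi grid must be increasing")
        if self.nu_values.ndim != 1 or np.any(self.nu_values < 0):
            raise InvalidParameterError("nu grid must be 1-D and nonnegative")
        if self.prior_weights is not None:
            w = np.asarray(self.prior_weights, dtype=float)
            if w.shape != (self.phi_values.size, self.nu_values.size):
                raise InvalidParameterError("prior_weights shape must be (nphi, nnu)")
            if np.any(w < 0) or w.sum() <= 0:
                raise InvalidParameterError("prior weights must be nonnegative, not all zero")
            self.prior_weights = w / w.sum()
        if self.sigma2_values is not None:
            s = np.asarray(self.sigma2_values, dtype=float)
            if s.ndim != 1 or np.any(s <= 0):
                raise InvalidParameterError("sigma2 grid must be 1-D and positive")
            self.sigma2_values = s

    @property
    def shape(self) -> tuple[int, int]:
        return (self.phi_values.size, self.nu_values.size)

    def log_prior(self) -> np.ndarray:
        if self.prior_weights is None:
            return np.zeros(self.shape)
        with np.errstate(divide="ignore"):
            return np.log(self.prior_weights)


def default_grid(obs: ObservationSet, n_phi: int = 100, n_nu: int = 100) -> ParameterGrid:
    """Flat-prior grid sized to the data's pairwise-distance support."""
    d = pairwise_distances(obs.coords)
    pos = d[d > 0]
    if pos.size == 0:
        raise InvalidInputError("all observation locations coincide")
    return ParameterGrid(
        phi_values=np.linspace(pos.min(), d.max(), n_phi),
        nu_values=np.linspace(0.0, 2.0, n_nu),
    )


@dataclass
class DiscretePosterior:
    """Normalized discrete posterior over the parameter grid, with the
    per-cell conjugate conditionals needed for sampling and prediction."""

    obs: ObservationSet
    grid: ParameterGrid
    log_weights: np.ndarray  # (nphi, nnu) or (nphi, nnu, nsig), normalized
    beta_hat: np.ndarray  # (nphi, nnu)
    beta_prec: np.ndarray  # (nphi, nnu): F'V^-1 F (scalar, constant trend)
    s2: np.ndarray  # (nphi, nnu): GLS residual sum of squares
    df: int
    _eig_cache: dict = field(default_factory=dict, repr=False)

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @property
    def weights_phi_nu(self) -> np.ndarray:
        """(nphi, nnu) marginal weights (sums out any sigma2 axis)."""
        w = self.weights
        return w.sum(axis=2) if w.ndim == 3 else w

    @property
    def mode(self) -> tuple[int, int]:
        """(i_phi, i_nu) of the maximum-probability cell; ties break to the
        lowest lexicographic index."""
        w = self.weights_phi_nu
        return np.unravel_index(int(np.argmax(w)), w.shape)  # type: ignore[return-value]

    def eig(self, i_phi: int) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of R(phi_i) for the data locations."""
        if i_phi not in self._eig_cache:
            d = pairwise_distances(self.obs.coords)
            R = np.exp(-d / self.grid.phi_values[i_phi])
            lam, Q = np.linalg.eigh(R)
            self._eig_cache[i_phi] = (np.maximum(lam, _EIG_FLOOR), Q)
        return self._eig_cache[i_phi]


@dataclass
class PredictiveMap:
    """Posterior predictive mean and variance over a set of targets."""

    mean: np.ndarray | RasterGrid
    variance: np.ndarray | RasterGrid
    n_draws: int
    seed: int | None = None


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean and 5%/95% quantile credible interval."""

    table: pd.DataFrame  # index: parameter; columns: mean, q05, q95

    def to_row(self, date: str | None = None, r2: float | None = None) -> dict:
        """Flat dict row mirroring the per-date parameter-summary tables."""
        row: dict = {"date": date}
        for par in self.table.index:
            for col in ("mean", "q05", "q95"):
                row[f"{par}_{col}"] = self.table.loc[par, col]
        if r2 is not None:
            row["r2"] = r2
        return row


# ---------------------------------------------------------------------------
# posterior computation


def _gls_pieces(lam, Q, y, nu):
    """GLS quantities in the eigenbasis of R(phi): returns
    (beta_hat, beta_prec, S2, logdetV, logdetM) for a constant trend."""
    w = 1.0 / (lam + nu)
    yt = Q.T @ y
    ft = Q.T @ np.ones_like(y)
    M = float(ft @ (w * ft))  # F'V^-1 F
    b = float(ft @ (w * yt))
    beta = b / M
    S2 = float(yt @ (w * yt)) - beta * b
    logdetV = float(np.sum(np.log(lam + nu)))
    return beta, M, max(S2, 0.0), logdetV, np.log(M)


def log_marginal_posterior(
    obs: ObservationSet,
    phi: float,
    nu: float,
    log_prior: float = 0.0,
) -> float:
    """Unnormalized log posterior density of one ``(phi, nu)`` cell.

    Flat prior on the constant trend beta, reciprocal prior on sigma2; both
    integrated analytically.
    """
    p = 1  # constant trend
    if obs.n <= p:
        raise DegenerateDataError(f"need n > {p} observations, got {obs.n}")
    if phi <= 0:
        raise InvalidParameterError("phi must be > 0")
    if nu < 0:
        raise InvalidParameterError("nu must be >= 0")
    d = pairwise_distances(obs.coords)
    lam, Q = np.linalg.eigh(np.exp(-d / phi))
    lam = np.maximum(lam, _EIG_FLOOR)
    beta, M, S2, logdetV, logdetM = _gls_pieces(lam, Q, obs.values, nu)
    if S2 <= 0:
        raise FittingFailedError("degenerate GLS residual (S^2 <= 0)")
    return log_prior - 0.5 * logdetV - 0.5 * logdetM - 0.5 * (obs.n - p) * np.log(S2)


def fit_discrete_posterior(obs: ObservationSet, grid: ParameterGrid | None = None) -> DiscretePosterior:
    """Evaluate the discrete posterior on every grid cell and normalize.

    Each phi's correlation matrix is eigendecomposed once; every nu (and
    sigma2) cell then costs O(n) on top of it.
    """
    p = 1
    if obs.n <= p:
        raise DegenerateDataError(f"need n > {p} observations, got {obs.n}")
    if grid is None:
        grid = default_grid(obs)
    n_phi, n_nu = grid.shape
    beta_hat = np.empty((n_phi, n_nu))
    beta_prec = np.empty((n_phi, n_nu))
    s2 = np.empty((n_phi, n_nu))
    lw2 = np.full((n_phi, n_nu), -np.inf)
    log_prior = grid.log_prior()
    df = obs.n - p

    d = pairwise_distances(obs.coords)
    eig_cache: dict = {}
    for i, phi in enumerate(grid.phi_values):
        lam, Q = np.linalg.eigh(np.exp(-d / phi))
        lam = np.maximum(lam, _EIG_FLOOR)
        eig_cache[i] = (lam, Q)
        yt = Q.T @ obs.values
        ft = Q.T @ np.ones(obs.n)
        for j, nu in enumerate(grid.nu_values):
            w = 1.0 / (lam + nu)
            M = float(ft @ (w * ft))
            b = float(ft @ (w * yt))
            beta = b / M
            S2 = float(yt @ (w * yt)) - beta * b
            beta_hat[i, j] = beta
            beta_prec[i, j] = M
            s2[i, j] = S2
            if M > 0:
                lw2[i, j] = (
                    log_prior[i, j]
                    - 0.5 * float(np.sum(np.log(lam + nu)))
                    - 0.5 * np.log(M)
                    - 0.5 * df * np.log(max(S2, _S2_FLOOR))
                )

    if not np.isfinite(lw2).any():
        raise FittingFailedError("posterior evaluation failed on every grid cell")

    if grid.sigma2_values is not None:
        # explicit sigma2 axis: weight ∝ pi(phi,nu) / sigma2 * p(y | phi,nu,sigma2),
        # times the sigma2 cell width so the discrete sum approximates the
        # continuous reciprocal-prior integral for any grid spacing
        sig = grid.sigma2_values
        nsig = sig.size
        if nsig > 1:
            edges = np.concatenate([[sig[0]], 0.5 * (sig[1:] + sig[:-1]), [sig[-1]]])
            log_dsig = np.log(np.diff(edges) + 1e-300)
        else:
            log_dsig = np.zeros(1)
        lw3 = np.full((n_phi, n_nu, nsig), -np.inf)
        for i in range(n_phi):
            lam, _ = eig_cache[i]
            for j, nu in enumerate(grid.nu_values):
                if not np.isfinite(lw2[i, j]):
                    continue
                base = (
                    log_prior[i, j]
                    - 0.5 * float(np.sum(np.log(lam + nu)))
                    - 0.5 * np.log(beta_prec[i, j])
                )
                lw3[i, j, :] = (
                    base - (0.5 * df + 1) * np.log(sig) - 0.5 * s2[i, j] / sig + log_dsig
                )
        lw = lw3 - logsumexp(lw3)
    else:
        lw = lw2 - logsumexp(lw2)

    post = DiscretePosterior(
        obs=obs,
        grid=grid,
        log_weights=lw,
        beta_hat=beta_hat,
        beta_prec=beta_prec,
        s2=s2,
        df=df,
    )
    post._eig_cache.update(eig_cache)
    return post


# ---------------------------------------------------------------------------
# sampling


def _sample_cells(post: DiscretePosterior, n_draws: int, rng: np.random.Generator):
    """Sample (i_phi, i_nu, sigma2, beta) for ``n_draws`` posterior draws."""
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    if post.df < 1:
        raise DegenerateDataError("df < 1; posterior draws undefined")
    w = post.weights
    flat = rng.choice(w.size, size=n_draws, p=w.ravel())
    if w.ndim == 3:
        i_phi, i_nu, i_sig = np.unravel_index(flat, w.shape)
        sigma2 = post.grid.sigma2_values[i_sig]
    else:
        i_phi, i_nu = np.unravel_index(flat, w.shape)
        # sigma2 | phi, nu ~ scaled-inv-chi2(df, S2/df)  ==  S2 / chi2_df
        sigma2 = post.s2[i_phi, i_nu] / rng.chisquare(post.df, size=n_draws)
    beta_sd = np.sqrt(sigma2 / post.beta_prec[i_phi, i_nu])
    beta = post.beta_hat[i_phi, i_nu] + beta_sd * rng.standard_normal(n_draws)
    return i_phi, i_nu, sigma2, beta


def draw_posterior_samples(
    post: DiscretePosterior,
    n_draws: int = _DEFAULT_NDRAWS,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Joint posterior draws of (phi, nu, sigma2, tau2, beta).

    Reproducible given ``seed``; pass a Generator to thread one RNG through
    a pipeline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i_phi, i_nu, sigma2, beta = _sample_cells(post, n_draws, rng)
    phi = post.grid.phi_values[i_phi]
    nu = post.grid.nu_values[i_nu]
    return pd.DataFrame(
        {
            "phi": phi,
            "nu": nu,
            "sigma2": sigma2,
            "tau2": nu * sigma2,
            "beta": beta,
            "i_phi": i_phi,
            "i_nu": i_nu,
        }
    )


# ---------------------------------------------------------------------------
# prediction


def _cell_predictor(post: DiscretePosterior, i_phi: int, i_nu: int, targets: np.ndarray):
    """Deterministic kriging pieces for one (phi, nu) cell.

    Returns ``(a, b, q)`` such that for a draw (sigma2, beta) in this cell
    the conditional mean at the targets is ``a + b * beta`` and the
    conditional variance ``sigma2 * (c0 - q)``.
    """
    lam, Q = post.eig(i_phi)
    nu = post.grid.nu_values[i_nu]
    phi = post.grid.phi_values[i_phi]
    w = 1.0 / (lam + nu)
    R0 = np.exp(-cdist(post.obs.coords, targets) / phi)  # (n, m)
    A = Q @ (w[:, None] * (Q.T @ R0))  # V^-1 R0
    a = A.T @ post.obs.values
    b = 1.0 - A.T @ np.ones(post.obs.n)  # f0 - R0' V^-1 F, constant trend
    q = np.einsum("nm,nm->m", R0, A)  # r0' V^-1 r0 per target
    return a, b, q


def krige_predict(
    post: DiscretePosterior,
    targets: np.ndarray | RasterGrid,
    n_draws: int = _DEFAULT_NDRAWS,
    seed: int | np.random.Generator | None = None,
    predict_signal: bool = True,
) -> PredictiveMap:
    """Posterior predictive mean/variance at target locations.

    For each posterior draw the conditional mean and variance are computed
    at every target; the map mean is the draw-average of conditional means
    and the map variance combines within-draw conditional variance and
    between-draw spread of the conditional mean (law of total variance).
    ``predict_signal=True`` predicts the noise-free surface S(x) (the
    default, as posterior-mean maps display a smooth field);
    ``predict_signal=False`` predicts a new noisy observation (adds the
    nugget to the conditional variance).
    """
    if post is None or not isinstance(post, DiscretePosterior):
        raise StateError("krige_predict requires a fitted DiscretePosterior")
    as_raster = isinstance(targets, RasterGrid)
    txy = targets.grid_points() if as_raster else np.atleast_2d(np.asarray(targets, dtype=float))
    if not np.isfinite(txy).all():
        raise InvalidInputError("target coordinates must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i_phi, i_nu, sigma2, beta = _sample_cells(post, n_draws, rng)

    m = txy.shape[0]
    sum_m = np.zeros(m)
    sum_m2 = np.zeros(m)
    sum_v = np.zeros(m)
    cells = np.unique(np.stack([i_phi, i_nu], axis=1), axis=0)
    for ip, iv in cells:
        sel = (i_phi == ip) & (i_nu == iv)
        k = int(sel.sum())
        a, b, q = _cell_predictor(post, int(ip), int(iv), txy)
        bsum = float(beta[sel].sum())
        b2sum = float((beta[sel] ** 2).sum())
        ssum = float(sigma2[sel].sum())
        # closed-form accumulation over the k draws in this cell:
        # m0 = a + b*beta  (constant trend, p = 1)
        sum_m += k * a + b * bsum
        sum_m2 += k * a**2 + 2 * a * b * bsum + b**2 * b2sum
        c0 = 1.0 if predict_signal else 1.0 + post.grid.nu_values[iv]
        sum_v += np.maximum(c0 - q, 0.0) * ssum

    mean = sum_m / n_draws
    var = sum_v / n_draws + np.maximum(sum_m2 / n_draws - mean**2, 0.0)
    var = np.maximum(var, 0.0)

    seed_out = seed if isinstance(seed, int) else None
    if as_raster:
        return PredictiveMap(
            mean=targets.like(mean.reshape(targets.data.shape)),
            variance=targets.like(var.reshape(targets.data.shape)),
            n_draws=n_draws,
            seed=seed_out,
        )
    return PredictiveMap(mean=mean, variance=var, n_draws=n_draws, seed=seed_out)


def predict_fixed_params(
    obs: ObservationSet,
    params: VariogramParams,
    targets: np.ndarray,
    predict_signal: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in conditional-Gaussian prediction at fixed parameters.

    The conditional mean/variance of ``S(x0)`` (or of a new observation)
    given the data, with (beta, sigma2, tau2, phi) known.  Used as the
    deterministic building block that the draw-averaged predictive maps
    integrate over, and convenient for oracle checks.
    """
    txy = np.atleast_2d(np.asarray(targets, dtype=float))
    if params.sigma2 <= 0:
        raise InvalidParameterError("predict_fixed_params requires sigma2 > 0")
    nu = params.nu
    d = pairwise_distances(obs.coords)
    V = np.exp(-d / params.phi) + nu * np.eye(obs.n)
    R0 = np.exp(-cdist(obs.coords, txy) / params.phi)
    A = np.linalg.solve(V, R0)
    resid = obs.values - params.beta
    mean = params.beta + A.T @ resid
    c0 = 1.0 if predict_signal else 1.0 + nu
    var = params.sigma2 * np.maximum(c0 - np.einsum("nm,nm->m", R0, A), 0.0)
    return mean, var


# ---------------------------------------------------------------------------
# summaries


def parameter_summaries(draws: pd.DataFrame) -> PosteriorSummary:
    """Posterior mean and quantile-based 5%/95% credible intervals.

    The noise-to-signal ratio NSR = tau2 / (tau2 + sigma2) is computed per
    draw and then summarized, so its interval respects the joint posterior.
    """
    if len(draws) < 2:
        raise InvalidInputError("need at least 2 draws to summarize")
    nsr = draws["tau2"] / (draws["tau2"] + draws["sigma2"])
    cols = {
        "beta": draws["beta"],
        "phi": draws["phi"],
        "sigma2": draws["sigma2"],
        "tau2": draws["tau2"],
        "nsr": nsr,
    }
    rows = []
    for name, s in cols.items():
        arr = np.asarray(s, dtype=float)
        rows.append(
            {
                "parameter": name,
                "mean": float(arr.mean()),
                "q05": float(np.quantile(arr, 0.05)),
                "q95": float(np.quantile(arr, 0.95)),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(table=table)
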