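"""Leave-one-out validation of kriged predictions.

For each site the held-out observation is predicted from the remaining
``n - 1`` sites.  By default (``refit=False``) the ``(phi, nu)`` posterior
fitted to the full data is reused and only the per-fold GLS conditionals
(beta_hat, S^2, df) and kriging weights are recomputed; ``refit=True``
re-runs the full grid fit on every fold.  Fit quality is summarized by the
ordinary least-squares regression of observed on predicted (with
intercept), whose R^2 is the statistic reported alongside each date's
parameter summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError, InvalidInputError, UndefinedFitError
from .kriging import DiscretePosterior, ObservationSet, ParameterGrid, fit_discrete_posterior

__all__ = ["FitQuality", "leave_one_out", "fit_quality"]

#: posterior cells are included until this cumulative mass is covered
_TOP_MASS = 1.0 - 1e-9


@dataclass(frozen=True)
class FitQuality:
    """Observed-on-predicted OLS fit: R^2, slope, intercept, n."""

    r2: float
    slope: float
    intercept: float
    n: int


def _select_cells(post: DiscretePosterior, rng=None, n_draws=None):
    """(i_phi, i_nu, weight) triples covering the bulk of the posterior.

    With ``n_draws`` set, cells and weights come from a posterior sample
    instead (Monte-Carlo mode); otherwise the exact top cells covering
    ``1 - 1e-9`` of the mass are used.
    """
    w = post.weights_phi_nu
    if n_draws:
        flat = rng.choice(w.size, size=n_draws, p=w.ravel())
        idx, counts = np.unique(flat, return_counts=True)
        weights = counts / n_draws
    else:
        order = np.argsort(w.ravel())[::-1]
        cum = np.cumsum(w.ravel()[order])
        k = int(np.searchsorted(cum, _TOP_MASS)) + 1
        idx = order[:k]
        weights = w.ravel()[idx]
        weights = weights / weights.sum()
    i_phi, i_nu = np.unravel_index(idx, w.shape)
    return i_phi, i_nu, weights


def _fold_predict(coords, y, target, phi_list, nu_list, weights, eig_by_phi):
    """Mixture-over-cells prediction of one held-out site.

    Per cell: GLS (beta_hat, S^2) on the fold's data, kriging conditional
    at the target, then Student-type predictive moments from the
    scaled-inverse-chi-square sigma2 conditional.  Cells are combined by
    their posterior weights via the law of total variance.
    """
    n = y.size
    df = n - 1
    mix_mean = 0.0
    mix_m2 = 0.0
    mix_var = 0.0
    ones = np.ones(n)
    for phi, nu, wt in zip(phi_list, nu_list, weights):
        lam, Q = eig_by_phi[phi]
        w = 1.0 / (lam + nu)
        yt = Q.T @ y
        ft = Q.T @ ones
        M = float(ft @ (w * ft))
        b = float(ft @ (w * yt))
        beta = b / M
        S2 = max(float(yt @ (w * yt)) - beta * b, 1e-300)
        r0 = np.exp(-cdist(coords, target).ravel() / phi)
        Ar = Q @ (w * (Q.T @ r0))
        a = float(Ar @ y)
        g = 1.0 - float(Ar @ ones)  # f0 - r0'V^-1 F
        q = float(r0 @ Ar)
        m0 = a + g * beta
        # predictive variance given (phi, nu), integrating beta and sigma2:
        # E[sigma2] * (c0 - q + g^2 / M), observation level (c0 = 1 + nu)
        e_sig2 = S2 / max(df - 2, 1)
        v0 = e_sig2 * (max(1.0 + nu - q, 0.0) + g * g / M)
        mix_mean += wt * m0
        mix_m2 += wt * m0 * m0
        mix_var += wt * v0
    var = mix_var + max(mix_m2 - mix_mean**2, 0.0)
    return mix_mean, var


def _loo_all_folds(post: DiscretePosterior, i_phi, i_nu, weights):
    """All leave-one-out predictions at once, per posterior cell, via the
    cross-validation identities of universal kriging.

    With ``B = V^-1 - V^-1 F (F'V^-1 F)^-1 F'V^-1`` (the trend-projected
    precision), deleting site i and re-kriging with a re-estimated GLS
    trend gives exactly

        mean_i = y_i - (B y)_i / B_ii
        var_i  = sigma2 / B_ii          (observation level, trend included)
        S2_{-i} = S2 - (B y)_i^2 / B_ii (the fold's GLS residual scale)

    so one factorization per (phi, nu) cell yields every fold.  sigma2 is
    integrated with its fold-specific scaled-inverse-chi-square mean; cells
    combine by posterior weight via the law of total variance.
    """
    obs = post.obs
    n = obs.n
    y = obs.values
    ones = np.ones(n)
    df_fold = n - 2  # fold size n-1, one trend coefficient
    mix_mean = np.zeros(n)
    mix_m2 = np.zeros(n)
    mix_var = np.zeros(n)
    for ip, iv, wt in zip(i_phi, i_nu, weights):
        lam, Q = post.eig(int(ip))
        nu = post.grid.nu_values[int(iv)]
        w = 1.0 / (lam + nu)
        Vi = Q @ (w[:, None] * Q.T)
        vo = Vi @ ones
        B = Vi - np.outer(vo, vo) / float(ones @ vo)
        By = B @ y
        Bii = np.maximum(np.diag(B), 1e-300)
        m = y - By / Bii
        S2_fold = np.maximum(post.s2[ip, iv] - By**2 / Bii, 1e-300)
        e_sig2 = S2_fold / max(df_fold - 2, 1)
        v = e_sig2 / Bii
        mix_mean += wt * m
        mix_m2 += wt * m * m
        mix_var += wt * v
    return mix_mean, mix_var + np.maximum(mix_m2 - mix_mean**2, 0.0)


def leave_one_out(
    obs: ObservationSet,
    grid: ParameterGrid | None = None,
    refit: bool = False,
    n_draws: int | None = None,
    seed: int | np.random.Generator | None = None,
    post: DiscretePosterior | None = None,
) -> pd.DataFrame:
    """Leave-one-out predictions for every site.

    Returns a DataFrame with columns ``site_id, observed, predicted_mean,
    predicted_sd``.  Pass a prefit ``post`` to skip the full-data fit.
    """
    if obs.n < 4:
        raise InsufficientDataError(f"leave-one-out needs n >= 4, got {obs.n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    if refit:
        for i in range(obs.n):
            fold = obs.drop(i)
            fpost = fit_discrete_posterior(fold, grid)
            i_phi, i_nu, weights = _select_cells(fpost, rng, n_draws)
            phis = fpost.grid.phi_values[i_phi]
            nus = fpost.grid.nu_values[i_nu]
            eig = {phi: fpost.eig(int(ip)) for phi, ip in zip(phis, i_phi)}
            m, v = _fold_predict(
                fold.coords, fold.values, obs.coords[i : i + 1], phis, nus, weights, eig
            )
            rows.append((obs.site_ids[i], obs.values[i], m, np.sqrt(v)))
    else:
        if post is None:
            post = fit_discrete_posterior(obs, grid)
        i_phi, i_nu, weights = _select_cells(post, rng, n_draws)
        mean, var = _loo_all_folds(post, i_phi, i_nu, weights)
        for i in range(obs.n):
            rows.append((obs.site_ids[i], obs.values[i], mean[i], np.sqrt(var[i])))

    return pd.DataFrame(rows, columns=["site_id", "observed", "predicted_mean", "predicted_sd"])


def fit_quality(observed: np.ndarray, predicted: np.ndarray) -> FitQuality:
    """OLS fit of observed on predicted (with intercept).

    R^2 is invariant under affine rescaling of the predictions; a
    zero-variance prediction vector leaves the fit undefined.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise InvalidInputError("observed and predicted must be equal-length 1-D arrays")
    if observed.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.ptp(predicted) == 0 or np.var(predicted) == 0:
        raise UndefinedFitError("predicted values have zero variance")
    res = stats.linregress(predicted, observed)
    return FitQuality(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=observed.size,
    )
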