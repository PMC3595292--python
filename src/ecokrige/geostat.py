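"""Exponential covariance structure and semivariogram computation.

The spatial model used throughout the package is a stationary, isotropic
Gaussian process with an exponential correlation function

    rho(h) = exp(-h / phi),

partial sill ``sigma2``, nugget ``tau2`` and range parameter ``phi``
(practical range of autocorrelation = 3 * phi).  The semivariogram of this
model is ``gamma(h) = tau2 + sigma2 * (1 - exp(-h / phi))`` for h > 0, with
``gamma(0) = 0`` by the usual nugget convention (a jump of size tau2 as
h -> 0+).

Distances are 2-D Euclidean on projected meter coordinates; anisotropy is
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "VariogramParams",
    "SemivariogramEstimate",
    "exp_correlation",
    "pairwise_distances",
    "build_covariance",
    "theoretical_semivariogram",
    "empirical_semivariogram",
    "cholesky_with_jitter",
]

#: Relative magnitude of the largest diagonal jitter ever applied before a
#: Cholesky factorization is declared to have failed.
MAX_JITTER_REL = 1e-8


@dataclass(frozen=True)
class VariogramParams:
    """One point in the exponential-model parameter space.

    Parameters
    ----------
    beta : float
        Constant trend mean, in units of the variable.
    sigma2 : float
        Partial sill (variance of the spatially structured process), >= 0.
    tau2 : float
        Nugget (measurement error plus sub-grid variation), >= 0.
    phi : float
        Range parameter in meters, > 0.  Practical range = 3 * phi.
    """

    beta: float
    sigma2: float
    tau2: float
    phi: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.beta, self.sigma2, self.tau2, self.phi]).all():
            raise InvalidParameterError("variogram parameters must be finite")
        if self.sigma2 < 0:
            raise InvalidParameterError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.tau2 < 0:
            raise InvalidParameterError(f"tau2 must be >= 0, got {self.tau2}")
        if self.phi <= 0:
            raise InvalidParameterError(f"phi must be > 0, got {self.phi}")

    @property
    def nu(self) -> float:
        """Relative nugget tau2 / sigma2 (dimensionless)."""
        if self.sigma2 == 0:
            return np.inf if self.tau2 > 0 else 0.0
        return self.tau2 / self.sigma2

    @property
    def total_sill(self) -> float:
        return self.sigma2 + self.tau2

    @property
    def nsr(self) -> float:
        """Noise-to-signal ratio tau2 / (tau2 + sigma2)."""
        tot = self.total_sill
        return 0.0 if tot == 0 else self.tau2 / tot

    @property
    def practical_range(self) -> float:
        """Distance at which correlation has decayed to exp(-3)."""
        return 3.0 * self.phi


@dataclass
class SemivariogramEstimate:
    """Binned empirical semivariogram (method-of-moments estimator)."""

    bin_centers: np.ndarray
    gamma_hat: np.ndarray  # NaN where a bin holds no pairs
    pair_counts: np.ndarray
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def nonempty(self) -> np.ndarray:
        return self.pair_counts > 0


def exp_correlation(h, phi: float):
    """Exponential correlation ``exp(-h / phi)``.

    ``h`` may be a scalar or array of nonnegative lag distances (m).
    """
    if phi <= 0:
        raise InvalidParameterError(f"phi must be > 0, got {phi}")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise InvalidInputError("lag distances must be nonnegative")
    out = np.exp(-h / phi)
    return out.item() if out.ndim == 0 else out


def pairwise_distances(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Euclidean distance matrix between two point sets (meters)."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = a if coords_b is None else np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("point sets must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidInputError("coordinates must be finite")
    return cdist(a, b)


def build_covariance(
    coords_a: np.ndarray,
    coords_b: np.ndarray | None,
    params: VariogramParams,
    add_nugget: bool = True,
) -> np.ndarray:
    """Covariance matrix ``sigma2 * exp(-h_ij / phi) (+ tau2 on the diagonal)``.

    The nugget is added on the diagonal only in the self-pair case
    (``coords_b is None``) and only when ``add_nugget`` is set: the nugget is
    white noise, uncorrelated between distinct locations.
    """
    self_pair = coords_b is None
    h = pairwise_distances(coords_a, coords_b)
    cov = params.sigma2 * np.exp(-h / params.phi)
    if add_nugget and self_pair:
        cov[np.diag_indices_from(cov)] += params.tau2
    return cov


def theoretical_semivariogram(h, params: VariogramParams):
    """Model semivariogram: 0 at h=0, ``tau2 + sigma2*(1 - exp(-h/phi))`` for h>0."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise InvalidInputError("lag distances must be nonnegative")
    gamma = params.tau2 + params.sigma2 * (1.0 - np.exp(-h / params.phi))
    gamma = np.where(h == 0, 0.0, gamma)
    return gamma.item() if gamma.ndim == 0 else gamma


def default_bin_edges(dmat: np.ndarray, n_bins: int = 13) -> np.ndarray:
    """Equal-width bins up to half the maximum pairwise distance."""
    dmax = dmat.max()
    if dmax <= 0:
        raise InvalidInputError("all points are coincident; no positive lags")
    return np.linspace(0.0, dmax / 2.0, n_bins + 1)


def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 13,
) -> SemivariogramEstimate:
    """Method-of-moments semivariogram: per bin, mean of (y_i - y_j)^2 / 2.

    Bins default to ``n_bins`` equal-width intervals up to half the maximum
    pairwise distance.  Bins with zero pairs get ``gamma_hat = NaN`` and a
    zero pair count.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    values = np.asarray(values, dtype=float)
    if coords.shape[0] < 2:
        raise InsufficientDataError("need at least 2 points for a semivariogram")
    if values.shape[0] != coords.shape[0]:
        raise InvalidInputError("coords and values length mismatch")
    if not np.isfinite(values).all():
        raise InvalidInputError("values must be finite")

    dmat = pairwise_distances(coords)
    iu = np.triu_indices(coords.shape[0], k=1)
    h = dmat[iu]
    sqd = 0.5 * (values[:, None] - values[None, :])[iu] ** 2

    if bin_edges is None:
        bin_edges = default_bin_edges(dmat, n_bins=n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise InvalidInputError("bin edges must be a 1-D increasing array")

    idx = np.digitize(h, bin_edges) - 1  # pairs outside [edge0, edgeN) are dropped
    nb = bin_edges.size - 1
    counts = np.zeros(nb, dtype=int)
    gam = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            gam[b] = sqd[sel].mean()
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return SemivariogramEstimate(centers, gam, counts, bin_edges=bin_edges)


def cholesky_with_jitter(mat: np.ndarray, max_rel_jitter: float = MAX_JITTER_REL) -> np.ndarray:
    """Lower Cholesky factor, adding a logged diagonal jitter if needed.

    Jitter grows geometrically from ``1e-12 * mean(diag)`` up to
    ``max_rel_jitter * mean(diag)``; failure beyond that raises LinAlgError.
    """
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(mat)))
    jitter = 1e-12 * scale
    while jitter <= max_rel_jitter * scale:
        try:
            out = np.linalg.cholesky(mat + jitter * np.eye(mat.shape[0]))
            logger.warning("applied diagonal jitter %.3e to achieve PSD", jitter)
            return out
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"matrix not PSD within jitter budget {max_rel_jitter:.1e} * diag scale"
    )
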