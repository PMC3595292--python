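"""Synthetic forested-catchment generator with known ground truth.

Emulates the structure of a small (~7.9 ha) temperate forested watershed:
terrain with ~51 m of relief, ~1800 trees of a dozen species with distinct
elevation/slope preferences and phenologies, a ~90-site sampling grid, and
coupled leaf-area-index (L) / soil-moisture (theta) fields over an
April-November season.  Every planted parameter (per-date variogram
parameters, the canopy-moisture coupling delay, species preferences) is
recoverable from the outputs, so the estimation modules can be tested
end-to-end without any field data.

Seasonal model
--------------
Per-species canopy curves are double-logistic in day-of-year (the standard
phenology form): a spring rise and an autumn decline whose product gives a
single rounded peak.  The watershed-mean curve of the abundance-weighted
species mixture is time-shifted once so that its maximum falls exactly on
the configured peak date.  Surface soil moisture follows

    theta(x, t) = baseline(x) - k * (L(x, t - lag) - L_min) + recharge(t) + residual

with a fixed default precipitation-pulse schedule (drier midsummer, as in a
drought year), canopy interception damping the recharge efficiency of
summer rain, and clipping to [0, saturation].  Spatial residuals are
Gaussian random fields whose (sigma2, tau2, phi) follow stylized seasonal
trajectories: L's nugget/sill rise toward midsummer then fall (with a dip
at full canopy closure), theta's do the opposite.

Random fields are simulated by dense Cholesky factorization (documented
limit ~5000 points); map-scale residuals are simulated on a coarse grid and
bilinearly upsampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError, InvalidParameterError
from .geostat import VariogramParams, cholesky_with_jitter, pairwise_distances
from .kriging import ObservationSet
from .density import TreeTable
from .raster import RasterGrid

__all__ = [
    "SpeciesConfig",
    "LandscapeConfig",
    "SeasonConfig",
    "Landscape",
    "simulate_grf",
    "make_terrain",
    "place_trees",
    "sample_sites",
    "generate_landscape",
    "simulate_canopy_series",
    "simulate_moisture_series",
    "simulate_watershed_means",
    "default_pulse_schedule",
    "truth_dict",
]

MAX_DENSE_POINTS = 5000


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SpeciesConfig:
    """One species: abundance, terrain preference, and phenology.

    ``elev_pref`` is in normalized elevation (0 = valley floor, 1 = ridge
    top); ``slope_pref`` in radians.  ``onset_mid`` / ``fall_mid`` are
    day-of-year midpoints of the spring rise and autumn decline of the
    double-logistic canopy curve; rates are per day.
    """

    code: str
    habit: str  # "deciduous" | "evergreen"
    abundance: float
    elev_pref: float
    elev_tol: float
    slope_pref: float
    slope_tol: float
    l_max: float
    onset_mid: float = 145.0
    onset_rate: float = 0.05
    fall_mid: float = 240.0
    fall_rate: float = 0.06
    l_winter_frac: float = 0.05  # leaf-off fraction of l_max


#: Default 12-species community: maples at low elevation, hickories at
#: moderate-to-high, oaks spanning the gradient (most abundant genus),
#: hemlock and white pine on the wet low-slope valley floor, Virginia pine
#: on the dry ridge.  Evergreens hold near-constant leaf area.
DEFAULT_SPECIES: tuple[SpeciesConfig, ...] = (
    SpeciesConfig("ACSA", "deciduous", 0.08, 0.25, 0.15, 0.30, 0.15, 4.5, onset_mid=138.0),
    SpeciesConfig("ACRU", "deciduous", 0.12, 0.20, 0.15, 0.28, 0.15, 4.7, onset_mid=133.0),
    SpeciesConfig("CACO", "deciduous", 0.05, 0.50, 0.15, 0.35, 0.15, 4.4, onset_mid=148.0),
    SpeciesConfig("CAGL", "deciduous", 0.07, 0.75, 0.15, 0.38, 0.15, 4.4, onset_mid=151.0),
    SpeciesConfig("CAOV", "deciduous", 0.05, 0.50, 0.15, 0.35, 0.15, 4.5, onset_mid=146.0),
    SpeciesConfig("CATO", "deciduous", 0.06, 0.80, 0.15, 0.38, 0.15, 4.4, onset_mid=155.0),
    SpeciesConfig("QUAL", "deciduous", 0.10, 0.30, 0.20, 0.35, 0.18, 4.6, onset_mid=144.0),
    SpeciesConfig("QUPR", "deciduous", 0.18, 0.80, 0.18, 0.40, 0.18, 4.5, onset_mid=158.0),
    SpeciesConfig("QURU", "deciduous", 0.12, 0.50, 0.20, 0.35, 0.18, 4.6, onset_mid=149.0),
    SpeciesConfig("TSCA", "evergreen", 0.07, 0.10, 0.10, 0.12, 0.10, 4.2),
    SpeciesConfig("PIST", "evergreen", 0.05, 0.15, 0.12, 0.15, 0.10, 4.0),
    SpeciesConfig("PIVI", "evergreen", 0.05, 0.85, 0.12, 0.15, 0.10, 3.9),
)


@dataclass
class LandscapeConfig:
    """Static landscape: domain, terrain, trees, sampling sites."""

    width: float = 316.0  # m (316 x 250 m ~ 7.9 ha)
    height: float = 250.0  # m
    cell: float = 1.0  # output raster resolution (m)
    coarse_cell: float = 10.0  # GRF / smoothing resolution (m)
    relief: float = 51.4  # m between highest and lowest point
    n_trees: int = 1832
    n_sites: int = 90
    species: tuple[SpeciesConfig, ...] = DEFAULT_SPECIES
    terrain_phi: float = 80.0  # range of the low-frequency terrain surface (m)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.cell <= 0:
            raise InvalidInputError("domain dimensions and cell size must be positive")
        n_cells = int(self.width / self.cell) * int(self.height / self.cell)
        if self.n_sites > n_cells:
            raise InvalidInputError("n_sites exceeds number of grid cells")
        ab = np.array([s.abundance for s in self.species])
        if ab.sum() <= 0:
            raise InvalidParameterError("species abundances must sum to a positive value")

    @property
    def area_ha(self) -> float:
        return self.width * self.height / 1e4


def _anchor_traj(anchors: dict[int, tuple[float, float, float]]):
    """Piecewise-linear (sigma2, tau2, phi) trajectory keyed by day-of-year."""
    doys = np.array(sorted(anchors))
    vals = np.array([anchors[d] for d in doys])

    def traj(doy: float) -> tuple[float, float, float]:
        s2 = float(np.interp(doy, doys, vals[:, 0]))
        t2 = float(np.interp(doy, doys, vals[:, 1]))
        ph = float(np.interp(doy, doys, vals[:, 2]))
        return s2, t2, ph

    return traj


#: Stylized per-date residual-field parameters (sigma2, tau2, phi) by DOY.
#: Order-of-magnitude matches to posterior means reported for a comparable
#: catchment: L's structure grows from budbreak toward midsummer with a dip
#: at full canopy closure; theta's variance shrinks as the watershed dries
#: and recovers in autumn.  Stylized defaults, not fitted values.
L_RESIDUAL_ANCHORS: dict[int, tuple[float, float, float]] = {
    105: (0.55, 0.04, 110.0),
    140: (1.40, 0.06, 150.0),
    160: (2.50, 0.06, 120.0),
    200: (0.27, 0.10, 157.0),
    230: (1.20, 0.05, 200.0),
    280: (0.80, 0.01, 180.0),
    330: (0.38, 0.005, 110.0),
}
THETA_RESIDUAL_ANCHORS: dict[int, tuple[float, float, float]] = {
    105: (0.0018, 0.0013, 197.0),
    150: (0.0020, 0.0013, 85.0),
    200: (0.0008, 0.0005, 90.0),
    255: (0.0006, 0.0004, 70.0),
    330: (0.0011, 0.0007, 66.0),
}


@dataclass
class SeasonConfig:
    """Seasonal dynamics: phenology window, coupling, recharge, residuals."""

    start: str = "2010-04-01"
    end: str = "2010-11-30"
    peak_date: str = "2010-07-19"  # watershed-mean L maximum
    lag_days: int = 11  # delay between canopy rise and moisture drawdown
    coupling_k: float = 0.05  # theta decrease per unit L (m3 m-3 per m2 m-2)
    theta_base: float = 0.28  # spring watershed-mean surface theta (m3 m-3)
    theta_sat: float = 0.45  # clipping ceiling
    valley_wetness: float = 0.04  # baseline theta excess of valley over ridge
    recharge_per_mm: float = 0.0005  # theta bump per mm effective rain
    recession_days: float = 3.0  # e-folding drainage time of recharge bumps
    interception: float = 0.75  # fraction of rain intercepted at full canopy
    l_noise_sd: float = 0.05  # observation noise on watershed-mean L
    theta_noise_sd: float = 0.004  # observation noise on watershed-mean theta
    depth_efold_cm: float = 45.0  # damping of surface anomalies with depth
    theta_deep: float = 0.24  # deep-profile resting moisture
    pulse_schedule: pd.DataFrame | None = None  # columns: date, mm
    l_anchors: dict = field(default_factory=lambda: dict(L_RESIDUAL_ANCHORS))
    theta_anchors: dict = field(default_factory=lambda: dict(THETA_RESIDUAL_ANCHORS))

    def __post_init__(self) -> None:
        if self.lag_days < 0 or self.coupling_k < 0:
            raise InvalidParameterError("lag_days and coupling_k must be nonnegative")
        if pd.Timestamp(self.start) >= pd.Timestamp(self.end):
            raise InvalidInputError("season start must precede end")
        if self.pulse_schedule is None:
            self.pulse_schedule = default_pulse_schedule(self.start, self.end)

    def l_params(self, doy: float) -> tuple[float, float, float]:
        return _anchor_traj(self.l_anchors)(doy)

    def theta_params(self, doy: float) -> tuple[float, float, float]:
        return _anchor_traj(self.theta_anchors)(doy)


def default_pulse_schedule(start: str, end: str) -> pd.DataFrame:
    """Deterministic precipitation-pulse schedule: one event every 8 days,
    with amounts suppressed in midsummer (a dry July-August, as in the
    drought year the defaults emulate).  ~450 mm over April-November."""
    dates = pd.date_range(start, end, freq="8D")
    doy = dates.dayofyear.to_numpy(float)
    mm = 12.0 - 9.0 * np.exp(-(((doy - 205.0) / 35.0) ** 2))
    return pd.DataFrame({"date": dates, "mm": mm})


# ---------------------------------------------------------------------------
# random fields


def simulate_grf(
    points: np.ndarray | RasterGrid,
    params: VariogramParams,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean Gaussian random field draw with exponential covariance.

    The structured component (partial sill sigma2, range phi) is drawn by
    dense Cholesky factorization; independent N(0, tau2) nugget noise is
    added per point.  Refuses more than ~5000 points (use a coarser grid
    and upsample).
    """
    as_raster = isinstance(points, RasterGrid)
    xy = points.grid_points() if as_raster else np.atleast_2d(np.asarray(points, dtype=float))
    m = xy.shape[0]
    if m > MAX_DENSE_POINTS:
        raise InvalidInputError(
            f"{m} points exceeds the dense-Cholesky limit {MAX_DENSE_POINTS}; "
            "simulate on a coarser grid and upsample"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros(m)
    if params.sigma2 > 0:
        C = params.sigma2 * np.exp(-pairwise_distances(xy) / params.phi)
        C[np.diag_indices_from(C)] += params.sigma2 * 1e-10  # pre-emptive jitter
        out += cholesky_with_jitter(C) @ rng.standard_normal(m)
    if params.tau2 > 0:
        out += np.sqrt(params.tau2) * rng.standard_normal(m)
    if as_raster:
        return out.reshape(points.data.shape)
    return out


def _coarse_grid(config: LandscapeConfig) -> RasterGrid:
    nc = max(int(round(config.width / config.coarse_cell)), 2)
    nr = max(int(round(config.height / config.coarse_cell)), 2)
    return RasterGrid(np.zeros((nr, nc)), 0.0, 0.0, config.coarse_cell)


def _fine_grid(config: LandscapeConfig) -> RasterGrid:
    nc = int(round(config.width / config.cell))
    nr = int(round(config.height / config.cell))
    return RasterGrid(np.zeros((nr, nc)), 0.0, 0.0, config.cell)


def _upsample(coarse: RasterGrid, fine: RasterGrid) -> np.ndarray:
    return coarse.sample(fine.grid_points()).reshape(fine.data.shape)


# ---------------------------------------------------------------------------
# terrain, trees, sites


def make_terrain(
    config: LandscapeConfig,
    seed: int | np.random.Generator | None = None,
    slope_method: str = "gradient",
) -> tuple[RasterGrid, RasterGrid]:
    """Elevation and slope rasters.

    Elevation is a V-shaped valley trend (a stream along the long axis,
    draining west) plus a smooth low-frequency random surface, linearly
    rescaled so max - min equals the configured relief.  Slope (radians) is
    the finite-difference gradient magnitude by default;
    ``slope_method="max_triangle"`` uses the eight-triangular-facet maximum
    slope instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coarse = _coarse_grid(config)
    pts = coarse.grid_points()
    trend = (
        0.9 * np.abs(pts[:, 1] - 0.45 * config.height) / config.height
        + 0.35 * pts[:, 0] / config.width
    )
    rough = simulate_grf(
        pts, VariogramParams(beta=0.0, sigma2=0.04, tau2=0.0, phi=config.terrain_phi), rng
    )
    surf = (trend + rough).reshape(coarse.data.shape)
    fine = _fine_grid(config)
    z = _upsample(coarse.like(surf), fine)
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        z = np.zeros_like(z)
    else:
        z = (z - zmin) / (zmax - zmin) * config.relief
    elev = fine.like(z)
    slope = fine.like(_slope_from_dem(z, config.cell, slope_method))
    return elev, slope


def _slope_from_dem(z: np.ndarray, cell: float, method: str) -> np.ndarray:
    if method == "gradient":
        gy, gx = np.gradient(z, cell)
        return np.arctan(np.hypot(gx, gy))
    if method == "max_triangle":
        # eight triangular facets per cell: each facet pairs a cardinal
        # neighbor step with the step from it to the adjacent diagonal
        nr, nc = z.shape
        zp = np.pad(z, 1, mode="edge")
        c = zp[1:-1, 1:-1]
        off = {
            "E": zp[1:-1, 2:], "W": zp[1:-1, :-2], "N": zp[:-2, 1:-1], "S": zp[2:, 1:-1],
            "NE": zp[:-2, 2:], "NW": zp[:-2, :-2], "SE": zp[2:, 2:], "SW": zp[2:, :-2],
        }
        facets = [
            ("E", "NE"), ("N", "NE"), ("N", "NW"), ("W", "NW"),
            ("W", "SW"), ("S", "SW"), ("S", "SE"), ("E", "SE"),
        ]
        best = np.zeros_like(c)
        for card, diag in facets:
            s1 = (c - off[card]) / cell
            s2 = (off[card] - off[diag]) / cell
            s2 = np.maximum(s2, 0.0)  # facet slope only counts downslope turn
            best = np.maximum(best, np.hypot(s1, s2) * (s1 > 0))
            best = np.maximum(best, np.abs(s1) * 0)  # keep dtype
        # uphill-everywhere cells fall back to max absolute cardinal slope
        fallback = np.max(np.stack([np.abs(c - off[k]) / cell for k in ("E", "W", "N", "S")]), axis=0)
        return np.arctan(np.where(best > 0, best, fallback))
    raise InvalidInputError(f"unknown slope method {method!r}")


def place_trees(
    config: LandscapeConfig,
    elevation: RasterGrid,
    slope: RasterGrid,
    seed: int | np.random.Generator | None = None,
) -> TreeTable:
    """Place ``n_trees`` trees; species drawn per tree with probability
    proportional to abundance x Gaussian suitability in (normalized
    elevation, slope) at that tree's location."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_trees
    xy = np.column_stack(
        [rng.uniform(0, config.width, n), rng.uniform(0, config.height, n)]
    )
    z = elevation.sample(xy)
    zn = (z - np.nanmin(elevation.data)) / max(np.nanmax(elevation.data) - np.nanmin(elevation.data), 1e-12)
    sl = slope.sample(xy)
    probs = np.empty((n, len(config.species)))
    for j, sp in enumerate(config.species):
        suit = np.exp(
            -0.5 * ((zn - sp.elev_pref) / sp.elev_tol) ** 2
            - 0.5 * ((sl - sp.slope_pref) / sp.slope_tol) ** 2
        )
        probs[:, j] = sp.abundance * suit
    tot = probs.sum(axis=1)
    if np.any(tot <= 0):
        raise InvalidParameterError("zero total species suitability at some location")
    probs /= tot[:, None]
    u = rng.random(n)
    idx = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    codes = np.array([sp.code for sp in config.species])
    habits = np.array([sp.habit for sp in config.species])
    return TreeTable(
        pd.DataFrame(
            {
                "tree_id": np.arange(n),
                "species": codes[idx],
                "x": xy[:, 0],
                "y": xy[:, 1],
                "habit": habits[idx],
            }
        )
    )


def sample_sites(
    config: LandscapeConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Stratified sampling-site layout: the domain is partitioned into a
    near-square grid of strata and one uniform point is drawn per stratum,
    giving even spatial coverage.  Returns columns site_id, x, y."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_sites
    kx = int(np.ceil(np.sqrt(n * config.width / config.height)))
    ky = int(np.ceil(n / kx))
    strata = [(i, j) for j in range(ky) for i in range(kx)]
    chosen = [strata[k] for k in rng.permutation(len(strata))[:n]]
    wx, wy = config.width / kx, config.height / ky
    xs = np.array([(i + rng.random()) * wx for i, _ in chosen])
    ys = np.array([(j + rng.random()) * wy for _, j in chosen])
    order = np.lexsort((xs, ys))
    return pd.DataFrame({"site_id": np.arange(n), "x": xs[order], "y": ys[order]})


@dataclass
class Landscape:
    """Generated static landscape bundle."""

    config: LandscapeConfig
    elevation: RasterGrid
    slope: RasterGrid
    trees: TreeTable
    sites: pd.DataFrame
    seed: int | None = None

    @property
    def site_coords(self) -> np.ndarray:
        return self.sites[["x", "y"]].to_numpy(float)


def generate_landscape(config: LandscapeConfig | None = None, seed: int | None = None) -> Landscape:
    """Terrain, trees and sampling sites from one seed."""
    config = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    elev, slope = make_terrain(config, rng)
    trees = place_trees(config, elev, slope, rng)
    sites = sample_sites(config, rng)
    return Landscape(config, elev, slope, trees, sites, seed=seed)


# ---------------------------------------------------------------------------
# phenology curves


def _double_logistic(doy, sp: SpeciesConfig) -> np.ndarray:
    doy = np.asarray(doy, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-sp.onset_rate * (doy - sp.onset_mid)))
    fall = 1.0 / (1.0 + np.exp(sp.fall_rate * (doy - sp.fall_mid)))
    return rise * fall


def _species_curve(doy, sp: SpeciesConfig, shift: float = 0.0) -> np.ndarray:
    d = np.asarray(doy, dtype=float) + shift
    if sp.habit == "evergreen":
        return sp.l_max * (0.85 + 0.15 * _double_logistic(d, sp))
    f = _double_logistic(d, sp)
    return sp.l_max * (sp.l_winter_frac + (1.0 - sp.l_winter_frac) * f)


def _peak_shift(config: LandscapeConfig, season: SeasonConfig) -> float:
    """Time shift aligning the abundance-weighted mixture maximum with the
    configured peak date (computed on a 0.05-day grid, deterministic)."""
    t = np.arange(60.0, 365.0, 0.05)
    mix = sum(sp.abundance * _species_curve(t, sp) for sp in config.species)
    t_star = t[int(np.argmax(mix))]
    return t_star - float(pd.Timestamp(season.peak_date).dayofyear)


def _mixture_curve(doy, config: LandscapeConfig, season: SeasonConfig) -> np.ndarray:
    shift = _peak_shift(config, season)
    ab = np.array([sp.abundance for sp in config.species])
    ab = ab / ab.sum()
    return sum(a * _species_curve(doy, sp, shift) for a, sp in zip(ab, config.species))


# ---------------------------------------------------------------------------
# watershed-mean daily series


def _recharge_series(dates: pd.DatetimeIndex, lbar: np.ndarray, season: SeasonConfig,
                     l_max: float) -> np.ndarray:
    """Daily recharge bump series from the pulse schedule: each event adds
    ``recharge_per_mm * mm * (1 - interception * L/Lmax)`` to surface theta,
    decaying with the configured recession time."""
    sched = season.pulse_schedule.set_index("date")["mm"]
    mm = sched.reindex(dates).fillna(0.0).to_numpy()
    eff = season.recharge_per_mm * mm * (1.0 - season.interception * np.clip(lbar / l_max, 0, 1))
    r = np.zeros(len(dates))
    decay = np.exp(-1.0 / season.recession_days)
    acc = 0.0
    for i in range(len(dates)):
        acc = acc * decay + eff[i]
        r[i] = acc
    return r


def simulate_watershed_means(
    config: LandscapeConfig | None = None,
    season: SeasonConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily watershed-mean series of L and surface theta.

    Returns a date-indexed frame with the deterministic truth (``L_det``,
    ``theta_det``), the noisy observed series (``L``, ``theta``), and the
    precipitation amounts (``precip_mm``).  theta responds to L with the
    configured delay: theta_det(t) depends on L_det(t - lag_days).
    """
    config = config or LandscapeConfig()
    season = season or SeasonConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = pd.date_range(season.start, season.end, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    l_det = _mixture_curve(doy, config, season)
    l_lag = _mixture_curve(doy - season.lag_days, config, season)
    l_min = float(_mixture_curve(np.array([60.0]), config, season)[0])
    l_max = float(l_det.max())
    recharge = _recharge_series(dates, l_det, season, l_max)
    theta_det = np.clip(
        season.theta_base - season.coupling_k * (l_lag - l_min) + recharge,
        0.0,
        season.theta_sat,
    )
    l_obs = np.clip(l_det + season.l_noise_sd * rng.standard_normal(len(dates)), 0.0, None)
    t_obs = np.clip(
        theta_det + season.theta_noise_sd * rng.standard_normal(len(dates)), 0.0, season.theta_sat
    )
    sched = season.pulse_schedule.set_index("date")["mm"]
    return pd.DataFrame(
        {
            "L_det": l_det,
            "theta_det": theta_det,
            "L": l_obs,
            "theta": t_obs,
            "precip_mm": sched.reindex(dates).fillna(0.0).to_numpy(),
        },
        index=dates,
    )


# ---------------------------------------------------------------------------
# spatial series


def _species_weight_maps(config: LandscapeConfig, trees: TreeTable, grid: RasterGrid) -> np.ndarray:
    """(n_species, nrows, ncols) local species-mixture weights on the coarse
    grid: smoothed tree counts per cell, regularized by overall abundance so
    treeless cells fall back to the landscape mixture."""
    nr, nc = grid.data.shape
    counts = np.zeros((len(config.species), nr, nc))
    col = np.clip((trees.coords[:, 0] // grid.cellsize).astype(int), 0, nc - 1)
    row = np.clip(
        nr - 1 - (trees.coords[:, 1] // grid.cellsize).astype(int), 0, nr - 1
    )
    code_idx = {sp.code: j for j, sp in enumerate(config.species)}
    for j, r, c in zip(trees.species.map(code_idx).to_numpy(), row, col):
        counts[j, r, c] += 1.0
    ab = np.array([sp.abundance for sp in config.species])
    ab = ab / ab.sum()
    for j in range(len(config.species)):
        counts[j] = gaussian_filter(counts[j], sigma=2.0) + 0.15 * ab[j]
    return counts / counts.sum(axis=0, keepdims=True)


def _date_doy(d) -> float:
    return float(pd.Timestamp(d).dayofyear)


def simulate_canopy_series(
    config: LandscapeConfig,
    season: SeasonConfig,
    landscape: Landscape,
    dates: list,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, RasterGrid], dict[str, ObservationSet]]:
    """Per-date L maps and site observations.

    Deterministic component: local species-mixture average of the
    per-species seasonal curves, smoothed to the grid.  Stochastic
    component: a date-specific smooth Gaussian random field (simulated on
    the coarse grid, bilinearly upsampled) plus iid nugget noise at the
    observation sites.  L is clipped at 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _check_dates(season, dates)
    coarse = _coarse_grid(config)
    fine = _fine_grid(config)
    weights = _species_weight_maps(config, landscape.trees, coarse)
    shift = _peak_shift(config, season)
    site_xy = landscape.site_coords
    maps: dict[str, RasterGrid] = {}
    site_obs: dict[str, ObservationSet] = {}
    for d in dates:
        key = str(pd.Timestamp(d).date())
        doy = _date_doy(d)
        per_sp = np.array([_species_curve(doy, sp, shift) for sp in config.species])
        det_coarse = np.tensordot(per_sp, weights, axes=(0, 0))
        s2, t2, phi = season.l_params(doy)
        smooth = simulate_grf(
            coarse.grid_points(), VariogramParams(0.0, s2, 0.0, phi), rng
        ).reshape(coarse.data.shape)
        field_coarse = coarse.like(det_coarse + smooth)
        maps[key] = fine.like(np.clip(_upsample(field_coarse, fine), 0.0, None))
        vals = field_coarse.sample(site_xy) + np.sqrt(t2) * rng.standard_normal(len(site_xy))
        site_obs[key] = ObservationSet(
            coords=site_xy,
            values=np.clip(vals, 0.0, None),
            site_ids=landscape.sites["site_id"].to_numpy(),
            date=key,
        )
    return maps, site_obs


def simulate_moisture_series(
    config: LandscapeConfig,
    season: SeasonConfig,
    landscape: Landscape,
    dates: list,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, RasterGrid], dict[str, ObservationSet], dict[str, pd.DataFrame]]:
    """Per-date surface-theta maps, site observations and depth profiles.

    theta(x, t) = baseline(x) - k * (L_det(x, t - lag) - L_min) +
    recharge(t) + residual field, clipped to [0, saturation].  The baseline
    is wetter on the valley floor.  Depth profiles damp the surface anomaly
    exponentially toward the deep resting moisture.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _check_dates(season, dates)
    coarse = _coarse_grid(config)
    fine = _fine_grid(config)
    weights = _species_weight_maps(config, landscape.trees, coarse)
    shift = _peak_shift(config, season)
    site_xy = landscape.site_coords

    z = landscape.elevation.sample(coarse.grid_points()).reshape(coarse.data.shape)
    zn = (z - z.min()) / max(z.max() - z.min(), 1e-12)
    baseline = season.theta_base + season.valley_wetness * (0.5 - zn)

    # daily watershed context for recharge and the L minimum
    daily = pd.date_range(season.start, season.end, freq="D")
    doy_daily = daily.dayofyear.to_numpy(float)
    lbar = _mixture_curve(doy_daily, config, season)
    recharge = pd.Series(
        _recharge_series(daily, lbar, season, float(lbar.max())), index=daily
    )
    l_min = float(_mixture_curve(np.array([60.0]), config, season)[0])

    maps: dict[str, RasterGrid] = {}
    site_obs: dict[str, ObservationSet] = {}
    profiles: dict[str, pd.DataFrame] = {}
    from .phenology import DEPTH_INTERVALS

    for d in dates:
        ts = pd.Timestamp(d)
        key = str(ts.date())
        doy = _date_doy(d)
        per_sp = np.array(
            [_species_curve(doy - season.lag_days, sp, shift) for sp in config.species]
        )
        l_lag_coarse = np.tensordot(per_sp, weights, axes=(0, 0))
        r = float(recharge.reindex([ts]).fillna(0.0).iloc[0])
        det = baseline - season.coupling_k * (l_lag_coarse - l_min) + r
        s2, t2, phi = season.theta_params(doy)
        smooth = simulate_grf(
            coarse.grid_points(), VariogramParams(0.0, s2, 0.0, phi), rng
        ).reshape(coarse.data.shape)
        field_coarse = coarse.like(det + smooth)
        maps[key] = fine.like(np.clip(_upsample(field_coarse, fine), 0.0, season.theta_sat))
        vals = field_coarse.sample(site_xy) + np.sqrt(t2) * rng.standard_normal(len(site_xy))
        vals = np.clip(vals, 0.0, season.theta_sat)
        site_obs[key] = ObservationSet(
            coords=site_xy,
            values=vals,
            site_ids=landscape.sites["site_id"].to_numpy(),
            date=key,
        )
        prof = {"site_id": landscape.sites["site_id"].to_numpy()}
        for depth in sorted(DEPTH_INTERVALS):
            damp = np.exp(-depth / season.depth_efold_cm)
            prof[f"theta_{depth}cm"] = np.clip(
                season.theta_deep + (vals - season.theta_deep) * damp, 0.0, season.theta_sat
            )
        profiles[key] = pd.DataFrame(prof)
    return maps, site_obs, profiles


def _check_dates(season: SeasonConfig, dates: list) -> None:
    lo, hi = pd.Timestamp(season.start), pd.Timestamp(season.end)
    for d in dates:
        ts = pd.Timestamp(d)
        if ts < lo or ts > hi:
            raise InvalidInputError(f"date {ts.date()} outside season {lo.date()}..{hi.date()}")


# ---------------------------------------------------------------------------
# ground truth


def truth_dict(config: LandscapeConfig, season: SeasonConfig, seed: int | None = None) -> dict:
    """All planted parameters, serializable to JSON, so recovery tests and
    downstream analyses are self-contained."""
    return {
        "seed": seed,
        "domain": {"width_m": config.width, "height_m": config.height,
                   "area_ha": config.area_ha, "relief_m": config.relief},
        "n_trees": config.n_trees,
        "n_sites": config.n_sites,
        "species": [asdict(sp) for sp in config.species],
        "season": {
            "start": season.start,
            "end": season.end,
            "peak_date": season.peak_date,
            "lag_days": season.lag_days,
            "coupling_k": season.coupling_k,
            "theta_base": season.theta_base,
        },
        "l_residual_anchors": {str(k): list(v) for k, v in season.l_anchors.items()},
        "theta_residual_anchors": {str(k): list(v) for k, v in season.theta_anchors.items()},
    }
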