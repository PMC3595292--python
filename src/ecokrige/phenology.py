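"""Seasonal time-series procedures: profile moisture storage, harmonization
of ground and remotely sensed canopy series, and the lagged regression that
quantifies the delay between canopy green-up and soil-moisture drawdown.

Time series are represented as :class:`pandas.Series` with a
``DatetimeIndex``; NaN marks missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    RescaleUndefinedError,
)

__all__ = [
    "DEPTH_INTERVALS",
    "ProfileMeasurement",
    "LagScanResult",
    "profile_storage",
    "harmonize_series",
    "lag_scan",
    "hysteresis_area",
]

#: Representative depth-interval length d_i (m) per measurement depth (cm).
#: 0.15 m for the 10 and 20 cm depths, 0.20 m for 40, 60, 80 and 100 cm.
DEPTH_INTERVALS: dict[int, float] = {10: 0.15, 20: 0.15, 40: 0.20, 60: 0.20, 80: 0.20, 100: 0.20}


@dataclass
class ProfileMeasurement:
    """Volumetric water content by depth at one site and date.

    ``theta_by_depth`` maps depth (cm, a subset of 10/20/40/60/80/100) to
    volumetric water content (m^3 m^-3); NaN entries are treated as missing.
    """

    theta_by_depth: dict[int, float]

    def __post_init__(self) -> None:
        bad = set(self.theta_by_depth) - set(DEPTH_INTERVALS)
        if bad:
            raise InvalidInputError(f"unknown measurement depth(s): {sorted(bad)}")


def profile_storage(profile: ProfileMeasurement | dict[int, float]) -> float:
    """Total profile soil moisture storage theta_TS = sum_i theta_i * d_i (m).

    Only depths with a finite theta contribute; theta must lie in [0, 1].
    """
    theta = profile.theta_by_depth if isinstance(profile, ProfileMeasurement) else profile
    if isinstance(profile, dict):
        ProfileMeasurement(theta)  # validate depths
    items = [(d, t) for d, t in theta.items() if np.isfinite(t)]
    if not items:
        raise InvalidInputError("profile has no valid measurements")
    for d, t in items:
        if not (0.0 <= t <= 1.0):
            raise InvalidInputError(f"theta at {d} cm outside [0, 1]: {t}")
    return float(sum(t * DEPTH_INTERVALS[d] for d, t in items))


def _as_series(s, name: str) -> pd.Series:
    if not isinstance(s, pd.Series):
        raise InvalidInputError(f"{name} must be a pandas Series with a DatetimeIndex")
    if not isinstance(s.index, pd.DatetimeIndex):
        raise InvalidInputError(f"{name} must have a DatetimeIndex")
    if s.empty:
        raise InvalidInputError(f"{name} is empty")
    if not s.index.is_monotonic_increasing or s.index.has_duplicates:
        raise InvalidInputError(f"{name} dates must be strictly increasing")
    return s.astype(float)


def harmonize_series(ground: pd.Series, remote: pd.Series) -> pd.Series:
    """Gapfill a ground-based series with a rescaled remote-sensing series.

    The remote series is rescaled by ``max(ground) / max(remote)`` so its
    peak matches the highest observed ground value; zeros in the remote
    series (sensor dropouts) are first replaced by linear interpolation
    between neighboring nonzero values.  Missing ground dates are then
    filled from the rescaled remote series (interpolated in time to the
    ground dates), residual gaps are linearly interpolated, and no value is
    extrapolated beyond the first/last date where either series has data.
    Unmasked ground observations are never altered.
    """
    ground = _as_series(ground, "ground")
    remote = _as_series(remote, "remote")
    if not ground.notna().any():
        raise InvalidInputError("ground series has no observed values")

    remote = remote.replace(0.0, np.nan)
    remote = remote.interpolate(method="time", limit_area="inside")
    rmax = remote.max()
    if not np.isfinite(rmax) or rmax == 0:
        raise RescaleUndefinedError("remote series maximum is zero or undefined")
    remote = remote * (ground.max() / rmax)

    # remote values on the ground dates (linear in time, no extrapolation)
    union = remote.reindex(remote.index.union(ground.index))
    union = union.interpolate(method="time", limit_area="inside")
    filled = ground.copy()
    gaps = filled.isna()
    filled[gaps] = union.reindex(ground.index)[gaps]
    # residual gaps: linear interpolation in time, interior only
    filled = filled.interpolate(method="time", limit_area="inside")
    return filled


@dataclass
class LagScanResult:
    """Per-lag regression table and the R^2-maximizing lag (days)."""

    table: pd.DataFrame  # columns: lag, slope, intercept, r2, n
    best_lag: int

    @property
    def best_row(self) -> pd.Series:
        return self.table.set_index("lag").loc[self.best_lag]


def _daily(series: pd.Series) -> pd.Series:
    """Interpolate onto a daily axis spanning the observed support."""
    obs = series.dropna()
    if obs.empty:
        raise InvalidInputError("series has no observed values")
    axis = pd.date_range(obs.index[0], obs.index[-1], freq="D")
    out = series.reindex(series.index.union(axis)).interpolate(method="time", limit_area="inside")
    return out.reindex(axis)


def lag_scan(
    L: pd.Series,
    theta: pd.Series,
    lags: range | list[int] = range(0, 31),
) -> LagScanResult:
    """Regress theta(t) on L(t - lag) for each integer-day lag.

    Both series are first linearly interpolated onto a common daily axis.
    The best lag maximizes R^2; ties break toward the smallest lag.  Lags
    with fewer than 3 overlapping pairs are flagged (NaN R^2) and excluded
    from best-lag selection.
    """
    Ld = _daily(_as_series(L, "L"))
    td = _daily(_as_series(theta, "theta"))
    rows = []
    for lag in lags:
        if lag < 0:
            raise InvalidInputError("lags must be nonnegative integer days")
        shifted = Ld.copy()
        shifted.index = shifted.index + pd.Timedelta(days=int(lag))
        paired = pd.concat([shifted.rename("L"), td.rename("theta")], axis=1).dropna()
        if len(paired) < 3 or paired["L"].var() == 0:
            rows.append({"lag": int(lag), "slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "n": len(paired)})
            continue
        res = stats.linregress(paired["L"], paired["theta"])
        rows.append(
            {
                "lag": int(lag),
                "slope": float(res.slope),
                "intercept": float(res.intercept),
                "r2": float(res.rvalue**2),
                "n": len(paired),
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["r2"])
    if valid.empty:
        raise InsufficientDataError("no lag had >= 3 overlapping pairs")
    best = int(valid.sort_values(["r2", "lag"], ascending=[False, True]).iloc[0]["lag"])
    return LagScanResult(table=table, best_lag=best)


def hysteresis_area(L: pd.Series, theta: pd.Series) -> float:
    """Signed area of the seasonal L-theta loop (shoelace formula).

    A descriptive index of hysteresis: the loop traced by the paired
    (L(t), theta(t)) trajectory over the season encloses zero area when the
    greening and browning branches coincide.  Positive sign means the loop
    is traversed counterclockwise in the (L, theta) plane.  This is an
    extension beyond the core analyses and is reported only on request.
    """
    Ld = _daily(_as_series(L, "L"))
    td = _daily(_as_series(theta, "theta"))
    paired = pd.concat([Ld.rename("L"), td.rename("theta")], axis=1).dropna()
    if len(paired) < 3:
        raise InsufficientDataError("need at least 3 paired dates")
    x = paired["L"].to_numpy()
    y = paired["theta"].to_numpy()
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
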