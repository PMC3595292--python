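"""Stage orchestration: simulate -> krige -> xval -> lagscan -> storage ->
density, with a JSON manifest recording config, seed, versions and
per-stage timing so every output is attributable and reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import fit_quality, leave_one_out
from .density import species_density_curves, values_at_trees
from .errors import InvalidInputError
from .io import (
    read_observations,
    read_timeseries,
    read_trees,
    write_observations,
    write_timeseries,
    write_trees,
)
from .kriging import (
    ParameterGrid,
    draw_posterior_samples,
    fit_discrete_posterior,
    krige_predict,
    parameter_summaries,
)
from .landscape import (
    LandscapeConfig,
    SeasonConfig,
    generate_landscape,
    simulate_canopy_series,
    simulate_moisture_series,
    simulate_watershed_means,
    truth_dict,
)
from .phenology import lag_scan, profile_storage
from .raster import RasterGrid, read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "krige", "xval", "lagscan", "storage", "density")

#: default measurement dates (one per roughly two weeks of the season)
DEFAULT_DATES = (
    "2010-04-25", "2010-05-20", "2010-06-17", "2010-07-19", "2010-07-30",
    "2010-08-28", "2010-09-26", "2010-10-19", "2010-11-13",
)


@dataclass
class RunConfig:
    """Workflow configuration; every field has a runnable default."""

    outdir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    dates: tuple[str, ...] = DEFAULT_DATES
    n_phi: int = 100
    n_nu: int = 100
    n_draws: int = 100_000
    lags: tuple[int, int] = (0, 30)
    prediction_cell: float = 10.0  # m, kriged-map resolution

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("stages", "dates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "lags" in raw:
            raw["lags"] = tuple(raw["lags"])
        return cls(**raw)


def _prediction_grid(cell: float, landscape_cfg: LandscapeConfig) -> RasterGrid:
    nc = int(round(landscape_cfg.width / cell))
    nr = int(round(landscape_cfg.height / cell))
    return RasterGrid(np.zeros((nr, nc)), 0.0, 0.0, cell)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write a manifest.

    Stage outputs land under ``outdir``; later stages read the files earlier
    stages wrote, so a stage whose inputs are missing raises a dependency
    error naming the producing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ecokrige",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    land_cfg = LandscapeConfig()
    season = SeasonConfig()
    rng = np.random.default_rng(config.seed)

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise InvalidInputError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        fn = {
            "simulate": _stage_simulate,
            "krige": _stage_krige,
            "xval": _stage_xval,
            "lagscan": _stage_lagscan,
            "storage": _stage_storage,
            "density": _stage_density,
        }[stage]
        info = fn(config, land_cfg, season, out, rng)
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = info
        logger.info("stage %s done in %.1fs", stage, info["seconds"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise InvalidInputError(f"missing input {path}; run the {producer!r} stage first")
    return path


def _stage_simulate(config, land_cfg, season, out: Path, rng) -> dict:
    land = generate_landscape(land_cfg, seed=config.seed)
    write_ascii_grid(land.elevation, out / "elevation.asc")
    write_ascii_grid(land.slope, out / "slope.asc")
    write_trees(land.trees, out / "trees.csv")
    land.sites.to_csv(out / "sites.csv", index=False)

    _, l_obs = simulate_canopy_series(land_cfg, season, land, list(config.dates), rng)
    _, t_obs, profiles = simulate_moisture_series(land_cfg, season, land, list(config.dates), rng)
    for date, obs in l_obs.items():
        write_observations(obs, out / f"obs_L_{date}.csv")
    for date, obs in t_obs.items():
        write_observations(obs, out / f"obs_theta_{date}.csv")
    for date, prof in profiles.items():
        prof.to_csv(out / f"profiles_{date}.csv", index=False)

    wm = simulate_watershed_means(land_cfg, season, rng)
    wm.rename_axis("date").to_csv(out / "watershed_means.csv")
    write_timeseries(wm["L"], out / "series_L.csv")
    write_timeseries(wm["theta"], out / "series_theta.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dict(land_cfg, season, seed=config.seed), fh, indent=2)
    return {"dates": list(config.dates), "n_sites": land_cfg.n_sites, "n_trees": len(land.trees)}


def _iter_obs_files(config, out: Path):
    for var in ("L", "theta"):
        for date in config.dates:
            yield var, date, out / f"obs_{var}_{date}.csv"


def _stage_krige(config, land_cfg, season, out: Path, rng) -> dict:
    rows = []
    targets = _prediction_grid(config.prediction_cell, land_cfg)
    for var, date, path in _iter_obs_files(config, out):
        obs, _ = read_observations(_require(path, "simulate"), date=date)
        post = fit_discrete_posterior(obs, _default_grid(obs, config))
        draws = draw_posterior_samples(post, config.n_draws, rng)
        rows.append(parameter_summaries(draws).to_row(date=date) | {"variable": var})
        pm = krige_predict(post, targets, n_draws=config.n_draws, seed=rng)
        write_ascii_grid(pm.mean, out / f"krige_{var}_{date}_mean.asc")
        write_ascii_grid(pm.variance, out / f"krige_{var}_{date}_var.asc")
    summary = pd.DataFrame(rows)
    cols = ["variable", "date"] + [c for c in summary.columns if c not in ("variable", "date")]
    summary[cols].to_csv(out / "parameter_summaries.csv", index=False)
    return {"n_fits": len(rows), "n_draws": config.n_draws}


def _default_grid(obs, config) -> ParameterGrid:
    from .kriging import default_grid

    return default_grid(obs, n_phi=config.n_phi, n_nu=config.n_nu)


def _stage_xval(config, land_cfg, season, out: Path, rng) -> dict:
    summaries = []
    for var, date, path in _iter_obs_files(config, out):
        obs, _ = read_observations(_require(path, "simulate"), date=date)
        loo = leave_one_out(obs, _default_grid(obs, config), seed=rng)
        fq = fit_quality(loo["observed"].to_numpy(), loo["predicted_mean"].to_numpy())
        loo.to_csv(out / f"xval_{var}_{date}.csv", index=False)
        summaries.append(
            {"variable": var, "date": date, "r2": fq.r2, "slope": fq.slope,
             "intercept": fq.intercept, "n": fq.n}
        )
    pd.DataFrame(summaries).to_csv(out / "xval_summary.csv", index=False)
    return {"n_fits": len(summaries)}


def _stage_lagscan(config, land_cfg, season, out: Path, rng) -> dict:
    L, _ = read_timeseries(_require(out / "series_L.csv", "simulate"))
    theta, _ = read_timeseries(_require(out / "series_theta.csv", "simulate"))
    res = lag_scan(L, theta, range(config.lags[0], config.lags[1] + 1))
    res.table.to_csv(out / "lag_scan.csv", index=False)
    return {"best_lag_days": res.best_lag, "best_r2": float(res.best_row["r2"])}


def _stage_storage(config, land_cfg, season, out: Path, rng) -> dict:
    rows = []
    for date in config.dates:
        prof = pd.read_csv(_require(out / f"profiles_{date}.csv", "simulate"))
        depth_cols = [c for c in prof.columns if c.startswith("theta_")]
        for _, r in prof.iterrows():
            theta = {int(c.split("_")[1].rstrip("cm")): r[c] for c in depth_cols}
            rows.append(
                {"date": date, "site_id": r["site_id"], "storage_m": profile_storage(theta)}
            )
    pd.DataFrame(rows).to_csv(out / "profile_storage.csv", index=False)
    return {"n_rows": len(rows)}


def _stage_density(config, land_cfg, season, out: Path, rng) -> dict:
    trees, _ = read_trees(_require(out / "trees.csv", "simulate"))
    n_curves = 0
    modes = []
    for name, path in (("elevation", out / "elevation.asc"), ("slope", out / "slope.asc")):
        raster = read_ascii_grid(_require(path, "simulate"))
        values = values_at_trees(raster, trees)
        curves = species_density_curves(values, trees)
        for sp, curve in curves.items():
            pd.DataFrame({"value": curve.grid, "density": curve.density}).to_csv(
                out / f"density_{name}_{sp}.csv", index=False
            )
            modes.append({"covariate": name, "species": sp, "mode": curve.mode,
                          "bandwidth": curve.bandwidth})
            n_curves += 1
    pd.DataFrame(modes).to_csv(out / "density_modes.csv", index=False)
    return {"n_curves": n_curves, "n_trees": len(trees)}
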