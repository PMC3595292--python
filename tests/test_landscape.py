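"""Synthetic landscape generator: random fields, terrain, trees, sites,
and the coupled canopy/moisture season."""

import json

import numpy as np
import pandas as pd
import pytest

from ecokrige import (
    LandscapeConfig,
    RasterGrid,
    SeasonConfig,
    VariogramParams,
    generate_landscape,
    make_terrain,
    place_trees,
    sample_sites,
    simulate_canopy_series,
    simulate_grf,
    simulate_moisture_series,
    simulate_watershed_means,
)
from ecokrige.density import density_curve
from ecokrige.errors import InvalidInputError
from ecokrige.geostat import empirical_semivariogram, theoretical_semivariogram
from ecokrige.landscape import (
    DEFAULT_SPECIES,
    SpeciesConfig,
    _slope_from_dem,
    default_pulse_schedule,
    truth_dict,
)


class TestSimulateGrf:
    def test_degenerate_params_give_zero_field(self, rng):
        pts = rng.uniform(0, 100, (30, 2))
        p = VariogramParams(0.0, 0.0, 0.0, 50.0)
        assert np.allclose(simulate_grf(pts, p, 0), 0.0)

    def test_pointwise_variance_matches_total_sill(self):
        p = VariogramParams(0.0, 1.2, 0.3, 50.0)
        pts = np.array([[10.0, 10.0], [200.0, 200.0]])
        draws = np.array([simulate_grf(pts, p, s) for s in range(800)])
        var = draws.var(axis=0)
        assert np.allclose(var, p.sigma2 + p.tau2, rtol=0.15)

    def test_semivariogram_tracks_theory(self):
        p = VariogramParams(0.0, 1.0, 0.1, 40.0)
        r = np.random.default_rng(3)
        pts = r.uniform(0, 250, (500, 2))
        y = simulate_grf(pts, p, r)
        est = empirical_semivariogram(pts, y)
        sel = (est.bin_centers > 15) & (est.bin_centers < 90) & est.nonempty
        theory = theoretical_semivariogram(est.bin_centers[sel], p)
        assert np.all(np.abs(est.gamma_hat[sel] / theory - 1) < 0.35)

    def test_reproducible_and_size_limited(self, rng):
        pts = rng.uniform(0, 10, (20, 2))
        p = VariogramParams(0.0, 1.0, 0.1, 5.0)
        assert np.allclose(simulate_grf(pts, p, 7), simulate_grf(pts, p, 7))
        with pytest.raises(InvalidInputError, match="coarser"):
            simulate_grf(np.zeros((5001, 2)), p, 0)


class TestTerrain:
    def test_relief_matches_configuration(self, small_landscape):
        z = small_landscape.elevation.data
        assert z.max() - z.min() == pytest.approx(
            small_landscape.config.relief, abs=1e-9
        )

    def test_flat_surface_has_zero_slope(self):
        assert np.allclose(_slope_from_dem(np.zeros((10, 12)), 1.0, "gradient"), 0.0)
        assert np.allclose(
            _slope_from_dem(np.zeros((10, 12)), 1.0, "max_triangle"), 0.0
        )

    def test_plane_slope_is_arctan_gradient(self):
        g = 0.25
        cols = np.arange(20.0)
        z = np.tile(g * cols, (15, 1))
        interior = _slope_from_dem(z, 1.0, "gradient")[1:-1, 1:-1]
        assert np.allclose(interior, np.arctan(g), atol=1e-12)
        mts = _slope_from_dem(z, 1.0, "max_triangle")[1:-1, 1:-1]
        assert np.allclose(mts, np.arctan(g), atol=1e-12)

    def test_default_relief(self):
        elev, slope = make_terrain(LandscapeConfig(), seed=1)
        assert elev.data.max() - elev.data.min() == pytest.approx(51.4)
        assert np.all(slope.data >= 0)


class TestTrees:
    def test_default_count(self):
        land = generate_landscape(LandscapeConfig(), seed=0)
        assert len(land.trees) == 1832

    def test_single_species_config(self, small_landscape):
        cfg = LandscapeConfig(
            width=120, height=100, cell=2.0, n_trees=50, n_sites=10,
            species=(SpeciesConfig("QUPR", "deciduous", 1.0, 0.8, 0.2, 0.4, 0.2, 4.5),),
        )
        trees = place_trees(cfg, small_landscape.elevation, small_landscape.slope, 0)
        assert set(trees.table["species"]) == {"QUPR"}

    def test_species_elevation_preferences_recovered(self):
        """Modes of the per-species elevation distributions order and track
        the planted preference modes."""
        land = generate_landscape(LandscapeConfig(), seed=0)
        z = land.elevation.sample(land.trees.coords)
        zn = (z - land.elevation.data.min()) / (
            land.elevation.data.max() - land.elevation.data.min()
        )
        prefs = {sp.code: sp.elev_pref for sp in DEFAULT_SPECIES}
        for code in ("ACRU", "QURU", "QUPR"):  # low / mid / high elevation
            sel = land.trees.table["species"].to_numpy() == code
            mode = density_curve(zn[sel]).mode
            assert abs(mode - prefs[code]) < 0.18
        low = density_curve(zn[land.trees.table["species"] == "ACRU"]).mode
        high = density_curve(zn[land.trees.table["species"] == "QUPR"]).mode
        assert low < high


class TestSites:
    def test_default_count_and_bounds(self):
        cfg = LandscapeConfig()
        sites = sample_sites(cfg, 0)
        assert len(sites) == 90
        assert sites["x"].between(0, cfg.width).all()
        assert sites["y"].between(0, cfg.height).all()

    def test_stratification_beats_uniform_spacing(self):
        """Minimum pairwise distance of stratified layouts exceeds uniform
        placement in most seeds."""
        from scipy.spatial.distance import pdist

        cfg = LandscapeConfig()
        wins = 0
        for s in range(20):
            strat = sample_sites(cfg, s)[["x", "y"]].to_numpy()
            r = np.random.default_rng(1000 + s)
            unif = np.column_stack(
                [r.uniform(0, cfg.width, 90), r.uniform(0, cfg.height, 90)]
            )
            wins += pdist(strat).min() > pdist(unif).min()
        assert wins >= 16  # >= 80% of seeds

    def test_too_many_sites_rejected(self):
        with pytest.raises(InvalidInputError):
            LandscapeConfig(width=10, height=10, cell=5.0, n_sites=100)


class TestSeason:
    def test_watershed_mean_peaks_on_configured_date(self, season):
        wm = simulate_watershed_means(LandscapeConfig(), season, seed=0)
        assert wm["L_det"].idxmax() == pd.Timestamp(season.peak_date)

    def test_moisture_minimum_trails_canopy_peak_by_lag(self, season):
        wm = simulate_watershed_means(LandscapeConfig(), season, seed=0)
        gap = (wm["theta_det"].idxmin() - wm["L_det"].idxmax()).days
        assert abs(gap - season.lag_days) <= 2

    def test_evergreen_only_config_is_near_constant(self):
        cfg = LandscapeConfig(
            species=tuple(sp for sp in DEFAULT_SPECIES if sp.habit == "evergreen")
        )
        wm = simulate_watershed_means(cfg, SeasonConfig(), seed=0)
        rel_range = (wm["L_det"].max() - wm["L_det"].min()) / wm["L_det"].max()
        assert rel_range < 0.2

    def test_spatial_sd_lower_at_peak_than_onset(self, season):
        land = generate_landscape(LandscapeConfig(), seed=0)
        maps, _ = simulate_canopy_series(
            land.config, season, land, ["2010-04-25", "2010-07-19"], seed=0
        )
        assert np.nanstd(maps["2010-07-19"].data) < np.nanstd(maps["2010-04-25"].data)

    def test_decoupled_limit_constant_moisture(self, small_landscape):
        empty_pulses = pd.DataFrame({"date": pd.to_datetime([]), "mm": []})
        flat = {105: (0.0, 0.0, 50.0), 330: (0.0, 0.0, 50.0)}
        season = SeasonConfig(
            coupling_k=0.0, pulse_schedule=empty_pulses, theta_anchors=flat
        )
        maps, obs, _ = simulate_moisture_series(
            small_landscape.config, season, small_landscape,
            ["2010-05-01", "2010-08-01"], seed=0,
        )
        assert np.allclose(maps["2010-05-01"].data, maps["2010-08-01"].data)

    def test_recharge_pulse_raises_moisture(self, season):
        one_pulse = pd.DataFrame(
            {"date": pd.to_datetime(["2010-06-15"]), "mm": [20.0]}
        )
        s = SeasonConfig(coupling_k=0.0, pulse_schedule=one_pulse)
        wm = simulate_watershed_means(LandscapeConfig(), s, seed=0)
        assert (
            wm.loc["2010-06-15", "theta_det"] > wm.loc["2010-06-14", "theta_det"]
        )

    def test_site_observations_reproducible(self, small_landscape, season):
        _, obs1 = simulate_canopy_series(
            small_landscape.config, season, small_landscape, ["2010-06-17"], seed=5
        )
        _, obs2 = simulate_canopy_series(
            small_landscape.config, season, small_landscape, ["2010-06-17"], seed=5
        )
        assert np.array_equal(
            obs1["2010-06-17"].values, obs2["2010-06-17"].values
        )

    def test_out_of_season_date_rejected(self, small_landscape, season):
        with pytest.raises(InvalidInputError):
            simulate_canopy_series(
                small_landscape.config, season, small_landscape, ["2010-01-15"], 0
            )

    def test_moisture_profiles_damp_with_depth(self, small_landscape, season):
        _, _, profiles = simulate_moisture_series(
            small_landscape.config, season, small_landscape, ["2010-07-19"], seed=0
        )
        prof = profiles["2010-07-19"]
        # midsummer drawdown: surface is drier; deep approaches resting value
        assert prof["theta_10cm"].mean() < prof["theta_100cm"].mean()
        assert abs(prof["theta_100cm"].mean() - season.theta_deep) < 0.02


class TestTruth:
    def test_truth_dict_is_json_serializable_and_complete(self, season):
        cfg = LandscapeConfig()
        blob = json.dumps(truth_dict(cfg, season, seed=3))
        truth = json.loads(blob)
        assert truth["season"]["lag_days"] == season.lag_days
        assert truth["n_trees"] == 1832
        assert truth["n_sites"] == 90
        assert len(truth["species"]) == 12
        assert truth["domain"]["area_ha"] == pytest.approx(7.9)

    def test_default_pulse_schedule_is_midsummer_dry(self):
        sched = default_pulse_schedule("2010-04-01", "2010-11-30")
        sched = sched.set_index("date")["mm"]
        july = sched[(sched.index.month == 7)].mean()
        may = sched[(sched.index.month == 5)].mean()
        assert july < may
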