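# ecokrige

Hierarchical Bayesian kriging and canopy–soil-moisture coupling analysis
for forested landscapes.

## The problem

In a small forested catchment, leaf area index (*L*, m² m⁻²) and volumetric
soil water content (*θ*, m³ m⁻³) are measured repeatedly on a sparse spatial
grid (~90 sites over ~8 ha) through a growing season. Two questions drive
the analysis: how do the spatial patterns of *L* and *θ* evolve from
budbreak through canopy closure to senescence, and with what delay does the
drying of surface soil follow the green-up of the canopy? The audience is
ecohydrologists and spatial statisticians who need full uncertainty on
interpolated maps and on the semivariogram parameters that describe spatial
structure — not just a point-estimate kriged surface.

## The model

Observations on one date are modeled as a constant-trend Gaussian process
with an exponential correlation function and a nugget:

    Y_i = β + S(x_i) + ε_i,      ε_i ~ N(0, τ²) iid
    S   ~ GP(0, σ² exp(−h/φ)),   practical range = 3φ

Priors are flat on β and on the discretized (φ, ν) pair, where ν = τ²/σ²
is the relative nugget, and reciprocal (scale-invariant) on σ². With
V = R(φ) + νI, the trend and scale integrate out analytically, leaving a
discrete posterior over the (φ, ν) grid:

    p(φ, ν | y) ∝ π(φ, ν) |V|^(−1/2) |FᵀV⁻¹F|^(−1/2) (S²)^(−(n−p)/2)

where S² is the GLS residual sum of squares. Conditionally,
σ² | φ, ν is scaled-inverse-χ² and β | σ² is Gaussian, so joint posterior
draws are exact. Each draw yields a conditional (kriging) mean and variance
at any target; maps combine draws by the law of total variance, so
parameter uncertainty propagates into the predictive variance. Reported
per-date summaries are posterior means with quantile-based 5%/95% credible
intervals for β, φ, σ², τ² and the noise-to-signal ratio
NSR = τ²/(τ²+σ²), plus a leave-one-out cross-validation R².

Around that core the package implements the season-scale procedures of the
analysis: depth-integrated profile moisture storage (θ_TS = Σ θᵢ dᵢ),
harmonization of ground and remotely sensed canopy series, an integer-day
lag scan regressing θ(t) on L(t−Δ), species–terrain kernel density curves
with mode extraction, and a synthetic landscape generator with known ground
truth that emulates the study's data structure end to end.

## Worked example

```python
import numpy as np
from ecokrige import (LandscapeConfig, SeasonConfig, generate_landscape,
                      simulate_canopy_series, simulate_watershed_means,
                      fit_discrete_posterior, draw_posterior_samples,
                      parameter_summaries, lag_scan)
from ecokrige.kriging import default_grid

config, season = LandscapeConfig(), SeasonConfig()
land = generate_landscape(config, seed=0)

# one date's site observations of L, kriging posterior, parameter summary
_, site_obs = simulate_canopy_series(config, season, land, ["2010-07-19"], seed=0)
obs = site_obs["2010-07-19"]
post = fit_discrete_posterior(obs, default_grid(obs, n_phi=40, n_nu=40))
draws = draw_posterior_samples(post, n_draws=20_000, seed=0)
print(parameter_summaries(draws).table.round(3))

# the canopy–moisture coupling delay from daily watershed-mean series
wm = simulate_watershed_means(config, season, seed=0)
scan = lag_scan(wm["L"], wm["theta"], range(0, 31))
print(f"best lag: {scan.best_lag} d  (R^2 = {scan.best_row['r2']:.3f})")
```

prints

```
              mean     q05      q95
parameter
beta         3.674   3.238    4.060
phi        201.745  68.325  349.718
sigma2       0.139   0.050    0.297
tau2         0.050   0.029    0.074
nsr          0.303   0.093    0.552
best lag: 11 d  (R^2 = 0.993)
```

At canopy closure the watershed mean of *L* is high (β ≈ 3.7) while its
spatially structured variance is small (σ² ≈ 0.14) — a closed, homogeneous
canopy — and the nugget fraction is correspondingly large. The lag scan
recovers an 11-day delay between canopy green-up and the decline of surface
soil moisture, which is the generator's planted coupling delay.

## Analysis drivers and CLI

`analysis/01_simulate_landscape.py` … `07_parameter_trajectories.py` run the
full analysis as a sequence of narrative steps (simulate → krige → validate
→ lag scan → storage → density curves → parameter trajectories), writing
tables under `results/analysis/`. The same stages are available as CLI
subcommands:

```sh
ecokrige run --seed 0 --out results/run
ecokrige lagscan --seed 0 --out results/run
```

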