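# Methods

## Spatial model

Each date's point observations are treated as one realization of a
constant-trend Gaussian process with exponential correlation and a nugget:
Y_i = β + S(x_i) + ε_i with S ~ GP(0, σ² exp(−h/φ)) and ε_i ~ N(0, τ²).
Distances are 2-D Euclidean on projected meter coordinates; the model is
isotropic and stationary, and each date is fitted independently (no
space–time covariance). The practical range of autocorrelation is 3φ. The
semivariogram is γ(h) = τ² + σ²(1 − exp(−h/φ)) for h > 0, with γ(0) = 0 and
a jump of size τ² as h → 0⁺ (the standard nugget convention; we state it
explicitly because the two limits are easy to conflate).

### Priors and the discrete posterior

The trend β carries a flat prior, σ² a reciprocal (scale-invariant) prior,
and the pair (φ, ν) with ν = τ²/σ² a discrete prior on a configurable grid
(default: 100 linearly spaced φ values spanning the data's nonzero
pairwise-distance support, 100 ν values on [0, 2], flat weights). β and σ²
integrate out in closed form, leaving per grid cell

    log p(φ, ν | y) = log π(φ, ν) − ½ log|V| − ½ log|FᵀV⁻¹F|
                      − ((n−p)/2) log S²  + const,

with V = R(φ) + νI in correlation scale, β̂ the GLS mean and S² the GLS
residual sum of squares. σ² is *not* given a third grid axis by default:
under the reciprocal prior its conditional is exactly scaled-inverse-χ²
with df = n − p and scale S²/df, so the analytic route is both exact and
cheaper than discretization. An explicit σ² axis
(`ParameterGrid(sigma2_values=...)`) is still provided for fidelity
experiments against fully gridded implementations; its cell weights include
the σ² cell widths so the discrete sum approximates the continuous
reciprocal-prior integral under any grid spacing.

A useful consequence of this prior structure, asserted in the tests: the
normalized posterior over (φ, ν) is invariant under affine data transforms
y → a·y + c.

### Numerics

For each φ the correlation matrix is eigendecomposed once
(R = QΛQᵀ, eigenvalues floored at 1e−12); every ν cell then costs O(n) via
V⁻¹ = Q(Λ+ν)⁻¹Qᵀ, which makes a 100×100 grid at n ≈ 90 a sub-second fit.
All posterior arithmetic is in the log domain with log-sum-exp
normalization. Covariance factorizations elsewhere use Cholesky with a
logged diagonal jitter capped at 1e−8 times the diagonal scale. Degenerate
(constant) data produce S² ≈ 0; log S² is floored so the posterior remains
computable, and the kriging mean then correctly returns the constant.
Posterior-mode reporting breaks ties toward the lowest (φ, ν) lexicographic
index.

### Prediction

Per posterior draw (φ, ν, σ², β), the conditional mean at target x₀ is
m₀ = f₀β + r₀ᵀV⁻¹(y − Fβ) and the conditional variance σ²(c₀ − r₀ᵀV⁻¹r₀),
with c₀ = 1 for the latent signal and 1 + ν for a new observation. Maps
default to the signal (posterior-mean maps display a smooth surface);
observation-level prediction is a flag. Draws are grouped by grid cell and
accumulated in closed form (the trend is a single coefficient, so per-cell
sums over draws reduce to first and second moments of β), then combined by
the law of total variance. The default draw count is 100,000; summaries in
the analysis drivers use 20,000, which leaves Monte-Carlo error far below
the credible-interval widths.

## Leave-one-out validation

With `refit=False` (default) the (φ, ν) posterior fitted to all n sites is
reused and only per-fold quantities are recomputed. For each retained cell
we use the exact cross-validation identities of universal kriging: with
B = V⁻¹ − V⁻¹F(FᵀV⁻¹F)⁻¹FᵀV⁻¹, deleting site i and re-kriging with a
re-estimated GLS trend gives mean_i = y_i − (By)_i/B_ii, variance
σ²/B_ii, and fold residual scale S²₋ᵢ = S² − (By)ᵢ²/B_ii — so one
factorization per cell yields every fold, with no leakage of the held-out
value into the fold's trend. Cells covering 1 − 1e−9 of the posterior mass
are combined by weight (law of total variance); passing `n_draws` switches
to sampled cells. `refit=True` re-runs the full grid fit per fold and is
provided because the convention (reuse vs refit) is genuinely ambiguous;
the default follows the common validation-routine convention and is exact
for the reused-posterior interpretation.

Fit quality is the R² of the ordinary least-squares regression of observed
on predicted (with intercept) — the "linear model fit" convention — not
1 − SSE/SST about the 1:1 line. It is therefore invariant under affine
rescaling of the predictions, which the tests assert.

## Seasonal procedures

**Profile storage.** θ_TS = Σ θᵢ dᵢ in meters, with representative interval
lengths dᵢ = 0.15 m at the 10 and 20 cm depths and 0.20 m at 40–100 cm.
Only depths with finite θ contribute; θ outside [0, 1] is a validation
error. Storage is linear in θ and bounded by Σdᵢ (0.90 m for the five
shallow depths, 1.10 m with 100 cm included).

**Series harmonization.** The remote canopy series is rescaled by a single
season-max ratio max(ground)/max(remote) (per the "highest observed value"
convention, not per-date matching); zeros in the remote series are treated
as dropouts and linearly interpolated before use. Missing ground dates are
filled from the rescaled remote series interpolated in time, residual gaps
by linear interpolation, and nothing is extrapolated beyond the observed
support. Unmasked ground observations are never altered.

**Lag scan.** Both series are linearly interpolated onto a common daily
axis (measurement dates are irregular and no alignment scheme is canonical,
so the simplest one is used and stated). For each integer lag Δ in 0–30
days, θ(t) is regressed on L(t−Δ); the reported lag maximizes R², with ties
broken toward the smallest Δ. Maximum-R² selection is our choice of
criterion; the alternative (visual alignment) is not reproducible. The
best lag is invariant under affine transforms of either series. A
descriptive hysteresis index (signed shoelace area of the seasonal L–θ
loop) is provided but off by default; it is an extension, not part of the
core analysis.

## Density curves

Covariate maps are sampled at tree locations bilinearly (nearest-neighbor
by flag), and per-species curves use a Gaussian KDE with Silverman's
bandwidth on a 512-point grid padded by three bandwidths — the defaults of
the standard density routine in the field's toolchain. The reported
"center" of a species' distribution is the global density argmax (ties to
the smallest value). The mode is affine-equivariant within one grid step.
A zero-variance sample yields a point-mass warning and a narrow spike
rather than an error.

## Synthetic landscape generator

The generator emulates the *structure* of the study system — it is the
package's test bed, not a calibrated model of any real catchment.

* **Domain and terrain:** 316 × 250 m (7.9 ha) at 1 m resolution; elevation
  is a V-shaped valley trend plus a smooth Gaussian-field surface, rescaled
  exactly to 51.4 m of relief; slope (radians) from the finite-difference
  gradient, with an eight-facet maximum-triangle-slope variant by flag.
* **Community:** 1,832 trees of 12 species placed with probability
  proportional to abundance × Gaussian suitability in normalized elevation
  and slope: maples low, hickories moderate-to-high, oaks spanning the
  gradient (most abundant), hemlock/white pine on the wet low-slope valley
  floor, Virginia pine on the dry ridge.
* **Sites:** 90 locations by stratified sampling (one uniform point per
  stratum of a near-square partition), giving the even coverage of a
  designed grid; its minimum spacing beats uniform placement in ≥80% of
  seeds (tested).
* **Phenology:** per-species double-logistic curves (product of a spring
  rise and an autumn decline) with staggered budbreak midpoints (maples
  earliest, chestnut oak latest) and near-constant evergreens. The
  abundance-weighted mixture is time-shifted once, deterministically, so
  the watershed-mean curve peaks exactly on the configured peak date
  (default 19 July). Spring values near L ≈ 1.3 on 25 April rising to
  ≈ 3.9 at peak match the emulated seasonal morphology.
* **Moisture:** θ(x,t) = baseline(x) − k·(L(x,t−Δ) − L_min) + recharge(t)
  + residual, clipped to [0, 0.45]. Defaults: k = 0.05 m³ m⁻³ per unit L,
  Δ = 11 days, valley floor 0.04 wetter than the ridge. The precipitation
  pulse schedule is a fixed (deterministic) default — one event every 8
  days with midsummer amounts suppressed, emulating a drought summer —
  and recharge efficiency is damped by canopy interception (75% at full
  canopy) with a 3-day recession. Depth profiles damp the surface anomaly
  exponentially (e-folding 45 cm) toward a deep resting moisture of 0.24.
* **Residual fields:** date-specific Gaussian random fields whose
  (σ², τ², φ) follow piecewise-linear trajectories anchored at a handful of
  days-of-year: canopy structure grows from budbreak toward midsummer, dips
  sharply at full canopy closure, and partially recovers in autumn;
  moisture structure does the opposite. Anchor values are
  order-of-magnitude matches to posterior means reported for a comparable
  catchment (θ sill ~10⁻³ m⁶ m⁻⁶, L sill ~0.3–2.5) — stylized defaults,
  not fitted values.
* **Simulation mechanics:** dense-Cholesky GRFs only, refused above 5,000
  points; map residuals are simulated on a 10 m grid and bilinearly
  upsampled; site observations add iid nugget noise on top of the smooth
  field. Everything is bit-reproducible given (config, seed), and all
  planted parameters serialize to a truth JSON alongside the outputs.

**What the generator does not emulate:** hydrological routing, interception
storage, radiation/energy balance, measurement-footprint differences
between instruments, anisotropy, and non-Gaussian residuals. Passing tests
therefore demonstrate correct inference under the stated model class and
realistic magnitudes — not calibrated fidelity to any particular field
data set.

## Problem sizes in the tests and drivers

The analysis drivers use a 40×40 parameter grid, 20,000 draws and 20 m
kriged maps; the tests use grids from 3×3 (oracle comparisons) to 30×30
(coverage study at n = 150 over 20 replicates) and a 500-site field for the
cross-validation sanity checks. These sizes keep the full chain at a
couple of minutes on one CPU while leaving Monte-Carlo error negligible
relative to the quantities asserted. The oracle tests compare against
independent brute-force computations (tensor quadrature over (β, σ²) for
the posterior; dense joint-covariance conditioning for prediction) at
tolerances of 1e−6 and 1e−8 respectively.

## Known limitations

* Constant trend only; covariate trends (elevation, slope) would need a
  wider design matrix and are out of scope.
* The exponential family only; Matérn/spherical alternatives are not
  implemented.
* The discrete (φ, ν) grid bounds are data-driven defaults; a posterior
  piled against a grid edge indicates the bounds should be widened, and no
  automatic widening is attempted.
* LOO predictive standard deviations under `refit=False` integrate σ² with
  the fold's own residual scale but reuse full-data posterior weights over
  (φ, ν); with `refit=True` the weights are fold-specific at ~n× the cost.
* KDE modes on flat-topped distributions wobble by roughly the kernel
  bandwidth; the tests bound the average across seeds rather than a single
  realization.
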