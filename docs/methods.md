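# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `socsnr`.

## Data model and series filtering

The unit of analysis is a SOC time series: repeated visits to one site,
each with a SOC concentration (g/kg) harmonized to a 10 cm reference
depth.  Multi-layer profiles are interpolated with a shape-preserving
piecewise cubic Hermite polynomial (PCHIP) whose knots sit at layer
midpoints; PCHIP cannot overshoot the knot values, which matters for a
quantity that must stay non-negative.  With two knots it reduces to
linear interpolation; requests outside the knot span raise rather than
extrapolate, because cubic extrapolation of sparse depth profiles is
unreliable.

Series pass three quality filters before any target is built:

1. **≥ 3 visits** (default `min_visits = 3`) — the minimum for a trend;
2. **≤ 30 m maximum pairwise relocation** (`max_dist_m = 30`) — revisits
   farther apart than a map pixel cannot be treated as the same location.
   Distance is great-circle (haversine on the WGS84 mean radius,
   6 371 008.8 m); at 30 m the difference from any projected distance is
   far below GPS error, but the choice is config-exposed;
3. **C/N-ratio standard deviation < 3.8** (`max_cn_sd = 3.8`) — a large
   C/N shift between visits indicates the samples do not measure the same
   soil body.  The SD uses the sample estimator (ddof = 1, configurable).
   Series lacking C/N fail the criterion conservatively; `require_cn =
   False` skips it for them instead.

Rejections are tagged with the first failed criterion, and filtering is
idempotent.  Observed targets from kept series: every ordered visit pair
yields a δ (n(n−1)/2 per series, including long-interval pairs), and each
series yields one β from the classic Theil–Sen estimator (median of all
pairwise slopes).  For three-visit series this coincides with any
library implementation; for long series, subsampling-based estimators in
common libraries can differ from the exact pairwise median.

## Distribution-capturing forest

`fit_forest` trains a standard random-forest regressor and additionally
indexes, per tree, the training-target values in each terminal leaf.  A
prediction pools the raw leaf values reached across all trees (one leaf
per tree) into a single multiset R:

- point prediction = mean(R) (pooled mean, *not* the mean of per-tree
  means; the two coincide when all leaves are singletons, and the package
  asserts that identity in its tests);
- uncertainty = population SD of R (ddof = 0 — R is treated as the full
  conditional ensemble, not a sample from it);
- prediction intervals = symmetric empirical quantile intervals of R,
  inclusive (type-7) quantile convention.

Pooling is unweighted: a leaf with more training values contributes more.
A Meinshausen-style variant that reweights each leaf by its inverse size
is available (`weighted=True`) but is not the default, since unweighted
pooling matches the "all terminal node values" reading of the prediction
distribution.

Default hyperparameters (200 trees, √p features per split, unlimited
depth, `min_samples_leaf = 5`) are ordinary regression-forest settings,
all exposed in the config.  Leaves must not be too small when calibrated
uncertainty matters: a leaf of k values can at best resolve quantiles at
resolution 1/k, so calibration-sensitive analyses use
`min_samples_leaf ≳ 40`.

## SNR scenarios

All five scenarios reduce to signal / noise with signal = |prediction|:

- **direct** (change-first, and the state model itself): noise = SD of
  the model's own pooled distribution;
- **state-first δ**: signal = |mean₁ − mean₀|, noise = √(sd₀² + sd₁²),
  treating the two state predictions as independent — forests treat rows
  independently, but spatially or temporally shared covariates can make
  this an underestimate of the true error correlation (a known
  assumption, not corrected here);
- **state-first β**: signal = |OLS slope through the per-step
  distribution means|; noise = SD (ddof = 1) of `n_draws = 200` Monte-Carlo
  slopes, each fit to one value drawn uniformly at random from every
  step's pooled values.  OLS (not Theil–Sen) is used for the signal so
  that signal and noise come from the same fitting procedure; a Theil–Sen
  flag exists.  For iid draws the MC noise converges to
  √(Σ xc_t² σ_t²)/S_xx (σ/√42 for equal σ at years {0, 3, 9}), which the
  tests verify against a 10⁶-draw run.

Zero-spread distributions make SNR undefined; scalar calls raise, batch
calls can return a flagged infinite-SNR sentinel (`allow_degenerate`).
SNR is scale-invariant and satisfies SNR < 1 ⇔ signal < noise by
construction.  SNR > 0.5 under a symmetry assumption is sometimes read as
"the distribution lies on one side of zero"; that claim is not valid for
unbounded distributions and the package never reports it as such.

Detectability is related to accuracy via the relative absolute error
RAE = |pred − obs| / |obs| (undefined at obs = 0; such rows are excluded
with a warning) and the Spearman rank correlation between SNR and RAE,
with quadrant counts around SNR = 1 and a configurable RAE threshold.

Land-cover stratification orders classes along the vegetation gradient
B → C → G → S → W (bareland, cropland, grassland, shrubland, woodland).
Transition codes are classified by their endpoints: equal first and last
letters (or a single repeated letter) → no change; a later endpoint →
increasing vegetation; an earlier one → decreasing.

## Calibration diagnostics

Accuracy: MAE, bias (pred − obs) and Lin's concordance correlation
coefficient with population moments.  Uncertainty:

- **PICP**: fraction of observations inside the closed symmetric interval
  per nominal level (ties count as covered — the pooled distributions are
  discrete);
- **QCP**: fraction of observations ≤ the predicted q-quantile, probing
  asymmetry; for symmetric quantile intervals,
  PICP(p) = QCP((1+p)/2) − QCP((1−p)/2) up to ties.

The default level grid is 0.05…0.95 in steps of 0.05.  Sharpness is the
mean and SD of interval widths at a level.

## Spatial aggregation

Cross-validation errors are standardized by their predicted uncertainty,
e\* = (obs − pred)/sd, assuming errors proportional to predicted sd;
second-order stationarity of e\* is assumed, not tested.  Their spatial
structure is summarized by a variogram fitted to Matheron semivariances
in equal-width distance bins with Cressie weights n/γ²
(`scipy.optimize.least_squares`, bounded).  Families: exponential
(default; `range_km` is the effective range, γ reaching 95% of its
structured rise) and spherical (exact range).  Fits with a negligible
structured component (partial sill < 5% of the sill or range below the
first bin) are flagged `pure_nugget`.  Bin width matters for the nugget:
bins wider than ~a quarter of the range fold short-range structure into
the first bin and bias the nugget upward, so round-trip analyses here use
2 km bins over a 40 km max lag.

The correlation function is ρ(h) = (sill − γ(h))/sill with ρ(0) = 1
exactly (γ(0) = 0 even in the presence of a nugget), clipped to [0, 1].
Aggregate uncertainty over a grid cell discretized by B pixel centers
(equal weights):

    sd_AOI = (1/B) · sqrt( Σ_s Σ_u sd_s · sd_u · ρ(h_su) )

evaluated exactly (chunked, no full B×B allocation) up to 50 000 pixels
per cell and by seeded uniform pair subsampling beyond.  Limits used as
oracles: ρ ≡ 1 gives mean(sd) (no reduction); ρ = identity gives
√(Σ sd²)/B, i.e. a 1/√B shrinkage; general ρ lies between.  `snr_grid`
tiles a regular pixel grid at each requested support (defaults 2.5, 10,
40, 200 km), computes per-cell aggregate signal |mean prediction|, noise
and SNR, and summarizes their distributions per support.  Distances are
planar km for projected grids and great-circle km for lon/lat point sets;
mixing is not supported.

## Synthetic survey generator

The generator emulates the *structure* of a LUCAS-like repeated survey,
not Europe's geography: `n_sites` sites uniform on a square domain
(default 100 km) mapped to lon/lat near 50° N; contiguous land-cover
patches by nearest-seed (Voronoi) assignment of 12 seeds; baseline SOC =
land-cover mean (10/15/22/28/40 g/kg along B→C→G→S→W) times a
mean-corrected lognormal anomaly driven by a Gaussian random field with
exponential correlation (effective range 20 km, log-sd 0.45) — survey SOC
distributions are strongly right-skewed, and the multiplicative form
keeps baselines positive.  Per-site true trends are Normal(0, 0.25²)
g/kg/yr, bounded below at −0.95·baseline/duration so a site cannot lose
more carbon than it holds (this also makes noise-free surveys exactly
linear, hence exactly recoverable by Theil–Sen).  Visits at the default
rounds 2009/2015/2018 add iid Normal(0, 2²) g/kg analytical + micro-scale
noise, truncated at 0 (a warning fires if > 1% of visits truncate),
coordinate jitter of 5 m, and per-site C/N ≈ Normal(12, 2²) with 0.5
visit jitter.  Gaussian fields use Cholesky factorization with 1e-9
diagonal jitter (exact to that tolerance; practical to ~20 k points).

Covariates come in three kinds: `static_*` correlated with baseline SOC,
`annual_*` (2000 through the last round) tracking the standardized true
state so their within-window trend correlates with the true β, and pure
`noise_*` columns.  Correlation strengths are parameters (default 0.9),
so information content is dial-able from perfect to none.  The truth
table (baseline, β, coordinates, land cover) suffices to compute every
recovery metric without re-simulation.

What the generator does **not** emulate: real covariate physics
(reflectance, SAR, climate), measurement-method changes between rounds,
preferential sampling, land-cover change over time (codes are constant
per site), and the heavy spatial heterogeneity of real surveys.  Passing
tests therefore demonstrate the *internal consistency* of the framework
— bookkeeping, propagation formulas, calibration under a correct model,
aggregation limits — not that real SOC change is detectable; on real
data the state model's CCC is far lower and SNR values are
correspondingly smaller.

Change features summarize each annual covariate over three inclusive
periods — the target's interval [start, end], the pre-period
[2000, start] and the full period [2000, end] — with mean, population SD
and OLS slope (9 features per covariate).  Whether period boundaries
should be inclusive is genuinely open; both ends inclusive was chosen
and is switch-able.  Feature selection (RSCFI-style) accumulates
impurity importances over repeated row-subsampled forest fits (defaults:
10 rounds, 50% subsample, keep the top columns reaching 95% cumulative
importance); the defaults are declared approximate rather than canonical.

## Problem sizes and determinism

Default analysis scales — 500–600 simulated sites, 150–200 trees,
200 Monte-Carlo draws, 5 000 points for variogram round trips, 32×32
pixel aggregation grids — were chosen as the smallest sizes at which the
statistical checks are stable; every stochastic stage derives from one
run-level seed, and reruns are byte-identical.

## Known limitations

- State-first noise assumes independent state predictions; shared
  covariates induce correlation the propagation ignores.
- The variogram range estimate at 5 000 points has substantial sampling
  spread (±25% is typical); nugget/sill is more stable.
- Pooled-leaf uncertainty is approximately calibrated only when leaves
  are large enough to resolve the conditional distribution.
- Directional inference (is the change positive?) is out of scope; SNR
  quantifies magnitude relative to uncertainty only.
- Administrative-unit (zonal) aggregation and bulk-density/stock
  conversion are not implemented.
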