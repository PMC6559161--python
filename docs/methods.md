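# Methods

This note records the statistical model, the synthetic-data design, and
the numerical and design choices behind `bgscale`, at the level of
detail a maintainer or reviewer needs to interpret its outputs.

## Diversity metrics

All metrics are abundance-weighted with basal area (m²) as the
abundance currency, aggregated per plot (duplicate plot × species rows
in the input CSV are summed, mirroring how subplot stems aggregate to
plot totals).

* **Effective species number** (Hill number, order q = 1):
  `D = exp(−Σ pᵢ ln pᵢ)` on within-unit basal-area shares. Natural log;
  the effective number is base-invariant. `D` ranges from 1 (monoculture)
  to species richness (perfect evenness).
* **Alpha** of a neighbourhood: the *median* per-plot `D` (even counts:
  arithmetic mean of the two central values).
* **Beta**: mean Bray–Curtis dissimilarity
  `d = 1 − 2 Σ min(aᵢ, bᵢ) / (Σa + Σb)` over all C(m, 2) unordered plot
  pairs, undefined (NaN, flagged) for single-plot neighbourhoods. The
  default computes `d` on raw basal areas, so larger plots weigh more;
  a `proportion` variant first normalises each plot to within-plot
  shares. Both are defensible operationalisations of abundance-weighted
  turnover; the choice is a config switch (`dissimilarity_variant`) with
  `basal_area` the recorded default.
* **Gamma**: `D` of the neighbourhood pooled species-wise into one
  community. A median over a single pooled value would be vacuous; the
  median enters only across thinning replicates downstream.

Neighbourhood membership is inclusive (distance ≤ radius) everywhere,
and every neighbourhood contains its focal plot. Guaranteed inequality,
asserted in tests: pooled gamma ≥ the basal-area-share-weighted
geometric mean of plot alphas (concavity of Shannon entropy).

## Elevation heterogeneity

Sample SD (n − 1 denominator, matching the default of mainstream
statistical environments) of all non-nodata raster cells whose *centre*
lies within the circular window — cell-centre membership with inclusive
boundary is order-independent and makes window value sets nested across
radii. Windows clipped by the raster edge, or containing nodata, are
kept and flagged (`truncated_window`), never silently dropped. A
`stride` option subsamples every k-th cell for very large windows;
stride 2 changes window SD by ≈ 1% (median) on smooth synthetic terrain
(quantified in tests), and the default is stride 1 (exact). Projected
coordinates use Euclidean distance; geographic mode uses haversine with
Earth radius 6,371 km.

## Spatial thinning

The "iterative search" for spatially separated plots is implemented as
a seeded random-order greedy maximal packing: shuffle, then accept each
plot ≥ `min_separation_km` (default 100) from all previously accepted
plots. Each accepted set is maximal for its scan order, and the
scan-order randomness across replicates is exactly the uncertainty the
percentile intervals summarize. Replicate i draws its generator from
`SeedSequence(master_seed, spawn_key=(i,))` — a counter-based split, so
any subset of replicates can be recomputed in any order, bit-identically.
Edge plots (closer than `edge_buffer_km`, default 100 km, to the region
boundary polygon) are removed before any neighbourhood or window is
built, so no retained focal plot has a systematically clipped window.
In geographic mode the plot-to-boundary distance is the haversine
distance to a densified boundary (vertices every ~0.01°), an
approximation adequate at the 100 km buffer scale.

## Regression models

Fitted per replicate × radius × diversity form on (elevation SD,
diversity) pairs of the replicate's plots; rows where that form's
response or the elevation SD is missing are dropped for that form only
(counts logged). Fits need n ≥ 3 and a non-constant predictor;
degenerate or non-converged replicates are counted and excluded from
summaries.

* **Gamma GLM, log link** (alpha and gamma diversity):
  y ~ Gamma(shape ν, mean μ), log μ = β₀ + β₁x. Coefficients by IRLS —
  for this family/link pair the IRLS weights are identically 1, so each
  step is a least-squares solve on the working response
  z = η + (y − μ)/μ; convergence when the relative deviance change is
  < 1e−8 (max 100 iterations). ν by profile maximum likelihood given
  β̂ (solving ln ν − ψ(ν) + 1 + mean(ln(y/μ) − y/μ) = 0 by Brent's
  method), capped at 1e8 for (near-)noiseless data where the likelihood
  increases without bound in ν. Asymptotic SEs from the information
  matrix (ν·XᵀX for β; n(ψ′(ν) − 1/ν) for ν).
* **Beta regression, logit link, constant precision** (beta diversity):
  y ~ Beta(μφ, (1−μ)φ), logit μ = β₀ + β₁x. Maximum likelihood in
  (β₀, β₁, ln φ) by L-BFGS with the analytic gradient, then Newton
  polishing (finite-difference Hessian of the analytic gradient) until
  the gradient norm is < 1e−6. Starting values: least squares on
  logit(y) for β, method of moments for φ. The likelihood trace is
  recorded and never decreases across accepted iterations (near the
  optimum a step that shrinks the gradient while moving the likelihood
  within float noise is also accepted). SEs from the observed
  information, delta method for φ. Responses touching 0 or 1 exactly
  (identical or fully disjoint communities) are first compressed with
  the boundary squeeze y′ = (y(n−1) + 0.5)/n; the squeeze is applied
  automatically in the pipeline, with n the replicate sample size, and
  logged.

**Standardized slope.** The figure-level quantity is "SDs of diversity
per metre of elevation SD". For a nonlinear link, refitting on a
standardized response is vacuous (a log-link slope is invariant to
rescaling y), so the package defines the standardized slope as the
marginal effect at the replicate-mean predictor divided by the
replicate SD of the raw (unsqueezed) response:
β₁·μ̂(x̄)/sd(y) (log link) and β₁·μ̂(x̄)(1−μ̂(x̄))/sd(y) (logit link).
This is dimensionally exact, comparable across forms and radii, and for
the gamma family numerically invariant to rescaling y (asserted in
tests). Undefined (flagged) when sd(y) = 0.

**Pseudo-R².** No single R² exists for non-Gaussian models; per family:
deviance fraction explained (1 − D/D₀) for the gamma GLM, and the
squared correlation between link-scale fitted values and logit(y) for
the beta regression. Both are package choices, stated here, not claims
about any other analysis.

**Replicate summaries.** Percentiles (2.5, 25, 50, 75, 97.5) of
standardized slopes over converged replicates, linear-interpolation
convention; median pseudo-R²; pointwise 2.5/97.5 percentile bands of
μ̂(x) on a 25-point grid spanning the observed elevation-SD range.

## Synthetic data

* **Terrain**: Gaussian random fields by spectral synthesis — iid
  Gaussian Fourier coefficients damped by f^(−s/2) with spectral
  exponent s, inverse FFT, then affine rescaling so the marginal mean
  and SD are hit exactly (hence the SD matches its target to float
  precision). Larger s → smoother, longer-range terrain. Defaults
  (s = 2.2, SD 500 m, 1 km cells) give mountainous relief with local
  1-km-window SDs of roughly 50–300 m.
* **Communities**: each of `pool_size` species receives an elevation
  optimum uniform over the surface's elevation range; suitability at a
  plot decays as exp(−Δ²/2b²) with niche breadth b; presence is a
  Bernoulli thin of suitability; realised basal area is suitability ×
  a lognormal draw. With `heterogeneity_effect` h > 0, the local
  breadth is b + h·SD₁ₖₘ (SD of elevation within a fixed 1 km window),
  so plots in rugged terrain sample more of the pool — a planted,
  tunable diversity–heterogeneity mechanism. Plots landing on nodata or
  with empty communities are dropped. The RNG is consumed identically
  regardless of data-driven branches, so outputs are seed-stable.
* **Direct response simulators** for both model families decouple the
  regression tests from the community mechanism entirely.

What the generator does **not** emulate: subplot structure and stem
measurement protocols of real inventories, coordinate fuzzing,
DEM void-filling artefacts, anisotropic or non-Gaussian terrain,
dispersal limitation and biotic interactions. Passing tests therefore
demonstrate the *pipeline's* statistical correctness and calibration,
not any empirical claim about real forests.

## Canonical experiments (`bgscale.experiments`)

Both use a 1,000 × 1,000 km region (a western-US-sized study area),
100 km edge buffer and 100 km minimum separation — giving thinned
subsamples of ~45–50 plots — at desk-scale replicate counts (200).

* **Null calibration** (`heterogeneity_effect = 0`): the niche breadth
  is set to 10× the terrain SD so suitability is essentially flat in
  elevation. This matters: with narrow niches, elevation *sorting* alone
  couples pooled gamma diversity to elevation SD (plots in rugged
  neighbourhoods span more of the gradient, so their union covers more
  of the pool) even with the breadth mechanism off. That is a real
  ecological pathway, not an artefact — but it is not the null
  hypothesis the calibration check is about, so the null design removes
  both pathways. Standardized-slope intervals should then cover zero.
* **Signal detection** (`heterogeneity_effect = 2`, breadth 100 m,
  pool 120, lognormal σ = 0.5): rugged-terrain plots support
  several-fold more species (the top-vs-bottom quartile richness
  contrast is ≈ +13 species, vs ≈ 0 with the mechanism off). Median
  standardized gamma slopes are positive at every radius and the beta
  slope at the largest radius is positive. Beta diversity at the
  smallest radius is noisy by construction — at realistic plot
  densities most 5-km neighbourhoods hold a single plot, so the beta
  model there fits on few observations; the positivity check is
  therefore anchored at the largest radius.

Problem sizes used throughout (plot counts, replicate counts, grid
sizes) are desk-scale choices that keep the full suite fast while
leaving every statistical property testable; the original-scale
replicate count (100,000) is reachable through `n_replicates`.

## Known limitations

* Single predictor only (elevation SD); no multi-variable geodiversity,
  no spatial autocorrelation correction beyond thinning.
* Constant precision in the beta regression; no variable-dispersion
  models.
* One CRS per run; no reprojection. Geographic-mode edge filtering uses
  a densified-boundary approximation.
* The windowed SD is exact (no pyramid approximation); very large
  windows on fine rasters are O(cells in window) per plot — use
  `stride` if that ever binds.
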