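# Methods

## The statistic

For one predator stomach with prey rows `(count_k, mass_k)`, the
biomass-weighted predator–prey mass ratio is

    mean_prey_mass = Σ_k count_k · mass_k / Σ_k count_k
    PPMR           = M_pred / mean_prey_mass

i.e. the abundance-weighted arithmetic mean of prey individual mass in the
denominator, every prey individual counted once. This is the package-wide
default; abundance-weighted *geometric* and biomass-weighted means are
provided as clearly named variants (`ppmr_core.geometric_mean_prey_mass`,
`biomass_weighted_mean_prey_mass`) and are never used implicitly. Stomachs
with no prey, or whose prey all lack usable mass estimates, yield no
observation — they are excluded, never imputed. All analyses model
`log10 PPMR`, so a temperature slope `b` back-transforms to a percent
change of `(10^b − 1)·100` per °C, compounding to `(10^(bΔT) − 1)·100`
across a span ΔT.

## Covariate matching

* **SST**: a stomach sampled in month *m* is matched to the monthly mean of
  month *m − 1* (January uses December of the previous year) for the grid
  cell containing the sampling position. Cell membership is a floor to the
  grid origin — no interpolation; bands are half-open `[low, high)` so
  boundary coordinates belong to the higher cell. Records with no covering
  cell/month are flagged unmatched and excluded downstream, never zero-filled.
* **Fishing effort**: annual hours for (year, ICES rectangle). The
  rectangle code follows the published ICES rule: 0.5° rows numbered from
  36° N, 1° columns lettered from 44° W (A spans 44–40° W with digits 0–3;
  B–M, skipping I, span 10° each with a digit per degree). Records without
  an effort value remain in the temperature-only dataset and are excluded
  from the fishing subset, so the fishing subset is always contained in the
  temperature dataset. Effort enters models as centred/scaled log10 hours;
  the standardization constants are recorded on the analysis table and
  reused when mapping tercile medians onto the model scale. Annual-value
  matching is the default; a multi-year rectangle mean is a deliberate
  non-default option.
* **Season**: Dec–Feb winter, Mar–May spring, Jun–Aug summer, Sep–Nov
  autumn, from the sampling month.

## Models

Each response (`log10` of PPMR, predator mass, mean individual prey mass,
prey count, prey richness) is fit as a linear mixed model with fixed
temperature (optionally effort and temperature × effort, optionally a
centred quadratic temperature term) and crossed Gaussian random intercepts
for ICES rectangle, season, and predator species. Crossed intercepts are
expressed through variance components on a single grouping (statsmodels
MixedLM). Choices that were genuinely open:

* **Estimation**: REML by default. Model comparison (linear vs quadratic)
  refits both candidates by ML, since REML likelihoods with different fixed
  effects are not comparable; AIC = 2k − 2·logLik with k counting fixed
  effects, variance components, and the residual variance; ties prefer the
  linear model.
* **Optimization**: variance components are internally sqrt-parameterized,
  which flattens the gradient near zero and can stall L-BFGS at poor
  optima; each model is therefore fit with both L-BFGS and Powell and the
  better restricted likelihood kept. Non-convergence is flagged on the
  result, never silently replaced.
* **Boundary behaviour**: when a grouping truly carries no variance, REML
  estimates sit on the zero boundary only for some realizations; small
  positive estimates (shifting fixed effects by well under one standard
  error) are expected finite-sample behaviour, not fitting failures.
* **Degenerate inputs**: groupings with fewer than two retained levels are
  dropped with a logged note; a (near-)constant response falls back to OLS
  and is flagged degenerate; with no random terms the same interface fits
  OLS exactly.
* **Observation-level effects**: a per-stomach random intercept is
  confounded with the residual when there is one row per stomach, so it is
  used only for responses modelled at stomach × size-class granularity.
* **Continuous nuisance covariates** (chlorophyll, salinity, depth, years
  since start): a "random effect of a continuous covariate" is not
  estimable as stated; when present these are handled as decile-binned
  categorical intercepts (default) or fixed nuisance covariates, with the
  choice recorded in the fit notes. Rows missing a nuisance covariate keep
  their other terms rather than being dropped (complete-case analysis is a
  config flag).
* **R²**: a conditional pseudo-R² — (fixed + random) variance over total —
  reported with its definition attached, since many mixed-model R²
  conventions exist.
* **p-values**: Wald t with the fitter's residual df, no multiple-testing
  correction.

Stratified trend lines evaluate the conditional temperature slope
`β_T + β_TxF · f̃` at the standardized log10 effort `f̃` of each
effort-tercile median; terciles split observations into equal-count bins
with remainders assigned to lower bins.

## Species-response classification

Per species with ≥ 30 observations (configurable), log10 individual body
mass is regressed on temperature with a rectangle random intercept,
falling back to simple regression when the grouping collapses (the method
used is recorded per species). Classification is two-sided at α = 0.05:
*no change* if p ≥ α, otherwise the slope's sign. Categories aggregate as
percent of species and percent of summed count × mass biomass, predators
and prey separately; the three categories always partition the analysed
species, so each column sums to 100 up to rounding.

## Ordination

Prey abundances are summed per family × rectangle; families below a
minimum total abundance (default 5) are dropped with a log entry.
Bray–Curtis dissimilarities among family profiles (optional fourth-root
transform, default off) are embedded by non-metric MDS — SMACOF from 20
random starts, 500 iterations, tolerance 1e-7, best solution kept —
reporting Kruskal stress-1. Configurations are centred, rotated to
principal axes and sign-fixed, making coordinates reproducible and
row-order invariant. Environmental vectors regress each per-family
covariate (abundance-weighted mean body mass, mean temperature, mean
effort; the modal size class is also computed) on the two axes; the arrow
is the normalised coefficient direction, with the regression R² and a
permutation p-value over row shuffles.

## Synthetic data generator

The generator emulates the joined structure of a diet-survey analysis: it
is a stochastic inverse of the analysis pipeline, not a mechanistic
foraging model.

* **Design**: 40 ICES rectangles in two adjacent 1° columns climbing from
  50° N; monthly SST per rectangle = a latitudinal base gradient spanning
  4–19 °C plus a ±1.5 °C seasonal cosine; the SST table includes the
  December before the first sampling year so the lag rule always finds its
  month. Effort per rectangle-year is log-normal (ln-scale mean 6.572,
  sd 0.543), calibrated so its terciles resemble the effort strata of
  heavily fished shelf seas (≈45–566 / 576–878 / 903–3479 h per year).
* **True models** (log10 scale): predator mass `2.3 + 0.0029·T` plus a
  species intercept (sd 0.25) and residual (sd 0.2); PPMR
  `β0 + β_T·T + β_F·f̃ + β_TxF·T·f̃` plus rectangle (sd 0.05), season
  (sd 0.05), species (sd 0.15) intercepts and residual (sd 0.3). The
  stomach's target mean prey mass is predator mass minus PPMR (log10), so
  the implied prey-mass model is the difference of the two; the
  `paper_preymass` preset calibrates through that identity. Variance
  magnitudes are the package's own choices for realistic signal-to-noise;
  no empirical variance components are claimed.
* **Prey items**: the number of prey rows is `1 + Poisson` around a mean of
  3 (optionally temperature/effort-dependent to plant count responses),
  counts per row `1 + Poisson(0.7)`, item masses log-normal around the
  stomach target and then rescaled so the abundance-weighted mean hits the
  target exactly. The per-stomach statistic therefore inverts the generator
  exactly — in noise-free mode PPMR equals `10^(β0 + β_T·T)` to rounding
  precision — and residual stomach-level noise is carried entirely by the
  explicit variance components.
* **Interaction calibration**: published per-stratum lines (slope 0.03 /
  intercept 2.2 at low effort; 0.10 / 1.7 at high) are converted to main
  and interaction coefficients through the tercile-median of a standard
  normal, `z = |Φ⁻¹(1/6)| ≈ 0.967`: `β_T = 0.065`, `β_TxF = 0.036`,
  `β_F = −0.258`, `β0 = 1.95`.
* **What it does not emulate**: digestion-state bias in prey masses,
  taxon-specific size distributions, spatial autocorrelation beyond the
  rectangle intercept, sampling-gear selectivity, or real coastline
  geometry. Recovery tests therefore demonstrate correctness of the
  estimation machinery under the stated model, not robustness to these
  real-data features.

## Problem sizes and numerical conventions

Recovery runs use 5,000 stomachs and 10 replicate seeds per preset —
enough for Monte-Carlo standard errors an order of magnitude below the
smallest calibrated effects; smaller fixtures back the unit tests. All
randomness flows from explicit integer seeds (one root seed in the
pipeline), and identical configurations reproduce byte-identical outputs.
Size classes use half-open-upward boundaries at 0.072 g and 1.25 g by
default, with an empirical abundance-tercile mode since such boundaries
are ordinarily data-derived.

## Known limitations

* The per-stratum slopes of the calibrated interaction preset are exact at
  the *population* tercile medians of standardized log effort; empirical
  medians of a finite rectangle-year pool deviate slightly (≈0.93 vs
  0.967), a visible but sub-tolerance source of recovery bias.
* A four-level season random effect is at the edge of estimability; its
  variance estimate is noisy and occasionally absorbs smooth seasonal
  structure.
* Prey counts and richness are modelled as log10 of strictly positive
  counts (empty cells dropped), not with count likelihoods.
* The species classifier tests each species independently at α = 0.05; no
  multiplicity correction, by design, so ≈5% of truly stable species are
  mislabelled.
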