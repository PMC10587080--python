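# Methods

This note documents the models, conventions and design choices behind
`stomacomm`, in the order data flow through the pipeline.

## Species-level traits

Stomatal density is the photograph-level count/area ratio averaged over
photographs (mean of ratios rather than pooled count over pooled area;
the two coincide for a constant field area, and the mean of ratios is
the safer choice when areas vary). Stomatal length is the mean of all
recorded lengths on a surface. For amphistomatous leaves, SD is summed
and SL averaged over surfaces *before* SPI is computed; hypostomatic
leaves pass their lower-surface values through.

**SPI unit convention.** SPI = SD·SL² mixes mm⁻² and µm²; the raw
product is 10⁻⁶ of the true epidermis-area fraction. The package
reports SPI as a percentage, i.e. SD·SL²·10⁻⁴, which matches the
conventional "% of epidermis" reading of the index (100 pores mm⁻² of
20 µm stomata → SPI = 4%). `stomatal_pore_index(..., scale="raw")`
returns the unscaled product for cross-study comparability; the chosen
scale never affects correlations, SES values or R², only the printed
magnitudes.

## Community-weighted moments

CWM/CWV/CWS/CWK are population (biased, non-excess) weighted moments,
computed exactly as their defining sums with no small-sample
correction. Consequences worth knowing:

- CWV ≥ 0 always, and CWK ≥ CWS² + 1 whenever defined, with equality
  for two-point communities (a symmetric two-species plot has CWK = 1).
- A single-species plot has CWV = 0 and *undefined* CWS/CWK, encoded as
  NaN and excluded from downstream fits and from across-plot means in
  the null model.
- Species present in a plot but missing a trait record are dropped from
  that plot with the remaining weights renormalized (no imputation);
  drops are logged. A plot losing all its species keeps a row with NaN
  moments.

The vectorized engine used by the null model evaluates the moments
through power sums of globally standardized trait values (numerically
equivalent to the centered sums at the tolerances tested, and stable
because standardization removes the large common offset).

## Trait-randomization null model

Trait values are shuffled across all species-site records; plot
composition and biomass weights stay fixed. Per trait the statistics of
interest are the across-plot variance of CWMs and the across-plot means
of CWV, CWS and CWK, each standardized against its null distribution
(sample n−1 variance and standard deviation throughout).

Conventions adopted where the procedure admits variants:

- **Joint permutation.** The (SD, SL, SPI) triplet of a record moves as
  one, so the density–size trade-off survives in the null and only
  community assembly is randomized. `joint=False` gives independent
  per-trait shuffles for sensitivity analysis.
- **Global pool for stratified runs.** Forest-only and grassland-only
  SES are computed on the stratum's plots while still permuting across
  the *full* record pool; `within_stratum=True` restricts the pool
  instead.
- **Raw scale.** Statistics are computed on raw moment values;
  `log_scale=True` feeds log(CWM)/log(CWV) into the statistics instead.
- Undefined plot moments (NaN) are excluded from the across-plot
  summaries on both the observed and null sides; a null distribution
  with zero spread yields an undefined SES with an explicit flag.

Calibration is part of the contract: under neutral assembly the
generator's record-level traits are exchangeable, so SES values pooled
over traits, moments and replicate datasets must be centered near 0
with unit-order spread. The acceptance suite checks the pooled mean
(±0.15 band) and pooled sd ([0.7, 1.3]) over 50 replicates of a
200-plot neutral dataset with 500 randomizations each — pooled, because
per-combination means over 50 replicates have a sampling sd of ≈0.14
and would reject a perfectly calibrated statistic far too often.

## Climate variables

From per-site monthly mean/min/max temperature, precipitation and PET
the package derives bio1–bio19, the UNEP aridity index MAP/PET, and
growing-season temperature/precipitation/aridity (23 climatic
variables), plus 7 soil variables (bulk density, total N, pH, sand,
silt, clay, moisture).

Dialect choices, all documented switches where tools differ:

- Quarters are the 12 *rolling* 3-month windows with December–January
  wraparound; extremes are selected by window sum (precipitation) or
  mean (temperature), ties broken by the earliest window.
- bio2 is the mean monthly diurnal range; bio4 is the sample standard
  deviation of monthly means × 100; bio15 is the plain CV of monthly
  precipitation × 100 (`cv_guard=True` switches the denominator to
  1 + bio12/12).
- The growing season is the longest circular run of months with mean
  temperature ≥ 5 °C and precipitation/PET ≥ 0.05 (months with zero PET
  fail the moisture condition); ties between equally long runs go to
  the run containing the warmest month, then the earliest start.

**The 27-variable model set.** The regression scans and the variance
partitioning use bio1–bio19 + aridity index + the 7 soil variables.
The growing-season summaries are derived and written to the site table
but enter no variable group: the mean/seasonality/extreme grouping
enumerates exactly the 20 climatic variables above, which fixes the
model set at 27. Under the temperature/precipitation/soil scheme,
bio1–bio11 are temperature, bio12–bio19 plus the aridity index are
precipitation (the index is a precipitation-dominated ratio and nearly
collinear with MAP), and the soil variables form the third group.

Each group is summarized by the first two axes of a PCA on standardized
variables (constant columns dropped with a warning; each component's
largest-magnitude loading is made positive so signs are reproducible).

## Mixed models, R² and partitioning

All fits are `response ~ 1 + predictors + (1|site)` by REML. With one
observation per plot, a plot-within-site level would be confounded with
the residual, so the site intercept is the identifiable random
structure. CWM and CWV responses are natural-log transformed first
(positivity-constrained, right-skewed); zero CWVs from single-species
plots become missing and are dropped per fit. R² and rankings are
invariant to the log base; fold ranges are always computed on raw
values.

The solver profiles the fixed effects and residual variance out of the
REML criterion, leaving a single parameter — the group/residual
variance ratio — found by a bracketed scalar search with closed-form
Woodbury per-group updates. This is exact for the single-random-
intercept class, runs in milliseconds, and cannot fail to converge the
way general-purpose multiparameter optimizers can; agreement with
statsmodels `MixedLM` and R `lme4` is pinned by tests (variance
components to ~10⁻⁴ relative or better on well-conditioned fixtures).
Predictors are standardized internally for conditioning and estimates
mapped back exactly. Singular fits (group variance at zero) are
retained and flagged. Wald z p-values are reported and labeled as such;
no multiple-testing correction is applied because rankings, not
corrected significance, are the scan's output.

Nakagawa R²: marginal = σ²_f/(σ²_f+σ²_α+σ²_ε) with σ²_f the sample
variance of the fixed-effect predictor; conditional adds σ²_α to the
numerator.

Hierarchical partitioning averages each predictor's incremental
marginal R² over all orderings of model entry, computed with Shapley
subset weights (2^p fits, p ≤ 10; the predictors are the per-group PC1
and PC2 scores). Contributions are summed within groups; the random
share is conditional − marginal R² of the full model; the remainder is
unexplained. Negative averaged contributions are truncated at zero and
the positive ones rescaled so shares sum to exactly 100%; raw values
are preserved in the output for audit. Because the variance components
are re-estimated per subset, incremental R² is additive only
approximately for orthogonal predictors (tested to within 2 percentage
points); the all-orderings identity itself is exact and tested to
10⁻⁹.

## Synthetic data generator

The generator emulates the survey design the pipeline targets:

- **Trait records.** One record per species × site, with
  log₁₀(SL) ~ U[log₁₀ 17, log₁₀ 47] (the observed stomatal-length
  span) and log₁₀(SD) = 4.3 − 1.3·log₁₀(SL) + N(0, 0.15), i.i.d.
  across records. Records are independent draws because the survey unit
  is the locally measured species-site combination; this is also what
  makes the neutral scenario exactly exchangeable under the record
  permutation and hence a valid calibration ground truth. The cost is
  that species identity carries no trait information across sites —
  real intraspecific variation is large but not total, so observed SES
  against real data may be more dispersed than this null suggests.
- **Sites.** A latent gradient drives mean annual temperature
  (≈ −6…22 °C) and log annual precipitation (≈ 150…1800 mm); monthly
  series are July-peaking sinusoids with site-specific amplitude,
  precipitation is monsoon-concentrated, PET is a positive increasing
  function of temperature, and soil texture/pH/N/moisture co-vary with
  the precipitation gradient (dry sites are sandier and more alkaline).
  The wettest sites become forest, reproducing the real confound
  between vegetation type and climate. The default layout is 57 sites:
  28 forest × 4 plots and 29 grassland × 8 plots (112 + 232).
- **Assembly.** Site optimum for standardized log₁₀(SD) is
  `env_effect_slope` × the standardized log-MAP score; species records
  enter a plot's sample with weight exp(−F(u − optimum)²/2), where F is
  `filtering_strength` (× `grassland_filter_factor` in grasslands, so
  the grassland-convergence scenario is one dial). F = 0 is uniform
  neutral sampling. Biomass weights are lognormal
  (sd `abundance_lognormal_sd`; 0 gives equal weights). The Gaussian
  filter kernel is a standard modeling choice, not a field estimate.
  Under it the expected CWM slope on the climate score is attenuated to
  F/(1+F) × `env_effect_slope`, which is the quantity the recovery
  tests check.
- **Streams.** One seed per dataset, split into named substreams
  (pool / environment / assembly), so changing the plot count does not
  perturb the species pool.

What the generator does **not** emulate: spatial structure and
dispersal limitation, phylogenetic trait conservatism, C₃/C₄
composition, filtering on stomatal length or SPI directly (both respond
only through the trade-off correlation with density), measurement
error, and cross-site species trait consistency (see above). Passing
tests therefore validate the machinery and its calibration, not any
claim about real vegetation.

## Problem sizes used in validation

Moment and window oracles run on 500–1000 random fixtures. Null-model
calibration uses 50 replicate datasets of 200 plots (20 sites × 10)
with 500 randomizations each, and the same design with strong filtering
(F = 5) for the direction check. Mixed-model closed-form checks use 300
sites × 10 observations; the partition oracle enumerates all 720
orderings of 6 predictors. The acceptance script runs the full chain at
the 57-site / 344-plot survey scale with 500 randomizations.

## Known limitations

- The SES machinery assumes at least two plots per stratum and drops
  strata below that with a warning rather than failing.
- Hierarchical partitioning refits 2^p models; p is capped at 10.
- p-values use Wald z statistics (no Satterthwaite/Kenward-Roger
  denominator degrees of freedom); with ≥ 20 sites the difference is
  immaterial for the ranking-oriented outputs here.
- PET is consumed as an input column; the package does not compute it
  from first principles.
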