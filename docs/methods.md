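# Methods

`sizeclines` implements a complete spatiotemporal body-size analysis for
multi-source small-mammal trait records — the kind of workflow used to
test Bergmann's rule (larger endotherms in colder climates) and
urbanization effects in the North American deer mouse (*Peromyscus
maniculatus*) — together with a synthetic study system whose generative
parameters are fully known, so every stage can be validated against
ground truth without downloading anything.

## The statistical model

Body size (body mass in grams, or head-body length in mm) is modelled
with Gaussian linear mixed models.

**Spatial suite.** Candidate fixed effects are drawn from {MAT, MAP,
sex, season, log population density}; every candidate carries crossed
random intercepts for ecoregion and data source:

    y_i = x_i' β + u_eco(i) + u_src(i) + ε_i,
    u_eco ~ N(0, σ²_eco),  u_src ~ N(0, σ²_src),  ε ~ N(0, σ²_e).

The source intercept absorbs systematic measurement differences between
digitized museum specimens (VertNet), the 1948–1950s census program
(NACSM), and live-capture surveys (NEON); live-capture head-body lengths
are known to read short, so NEON can be excluded per dataset variant.

**Temporal suite.** Adds a decade fixed effect (standardized numeric bin
index) and replaces the random part with a correlated random
(intercept, decade-slope) pair per 200-km spatial zone:

    y_i = x_i' β + a_z(i) + b_z(i)·decade_i + ε_i,
    (a_z, b_z) ~ N₂(0, Σ),  corr(a, b) = r.

The correlation r between zone intercepts and zone slopes is the
quantity of biological interest: a strong negative r means large-bodied
populations are shrinking while small-bodied ones grow. It is reported
two ways — the estimated covariance parameter and the Pearson
correlation of the per-zone conditional modes (BLUPs) — plus an
unpooled, per-zone OLS trend table for comparison.

All candidates are estimated by maximum likelihood (not REML) because
they differ in fixed effects and must share a comparable likelihood;
ML and REML likelihoods are never mixed. Fitting is delegated to
`statsmodels` `MixedLM` (crossed intercepts via the single-group
variance-components formulation; the intercept/slope pair via a
per-zone random-effects formula). Gradient optimizers occasionally stall
when a variance component sits at 0; the fitter falls back to Powell's
method, which reaches the boundary exactly (verified against the OLS
limit). Candidates are ranked by

    AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1),

where k counts fixed effects **plus** all variance/covariance
parameters plus the residual variance. Akaike weights are
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2). Variance explained follows the
Nakagawa decomposition: marginal R² = σ²_f /(σ²_f + σ²_r + σ²_e) and
conditional R² = (σ²_f + σ²_r)/(same), with σ²_f the variance of the
fixed-effect predictor and σ²_r the model-implied random-effect
variance averaged over the observed slope covariate.

The published candidate suites (29 spatial, 44 temporal) are not
itemized anywhere we could consume; the default enumeration is the full
subset lattice of the global model (32 and 64 candidates) and an
explicit candidate list can be supplied instead.

## Record harmonization

The cleaning pipeline applies, in order: coordinate presence → date
filters (complete and possible dates; "1 January" removed as a
year-only reporting artifact; records before 1895 removed) → sex filter
(only unambiguous female/male, case-insensitive; "female?",
"undetermined", empty all removed) → life-stage filter (only records
*labelled* juvenile are removed; "unknown" stays) → head-body length
derivation (HB = total − tail; anatomically impossible negative values
are nulled and flagged) → per-dataset measurement presence → 9 g adult
mass floor (strictly below 9 removed; 9.0 retained) → a single-pass
3-SD outlier rule computed per measurement (mass, tail, total) over the
current dataset, removing a record outlying in *any* measurement →
season and decade binning. Every step appends an audit entry
(step, in, removed, out); audits are conserved and chained by
construction.

Seasons use fixed equinox/solstice boundaries (Mar 20 / Jun 21 /
Sep 22 / Dec 21, both endpoints inclusive per season); the astronomical
dates wander by at most a day across years and a fixed table keeps the
assignment deterministic. Decades are ten-year bins anchored at 1895,
giving 13 bins for 1895–2019 with the last covering only 2015–2019.

Note a property of the 3-SD rule worth knowing: with n values and a
single gross outlier, the maximum standardized deviation is
(n−1)/√n, so at n ≤ 10 no single point can exceed 3 sample SDs
(masking). The rule is applied once, non-iteratively, as specified.

## Covariates

Each record is paired with the MAT/MAP grid-cell value of its
collection year and the natural-log human population density
(ln(d + 0.01), floor in persons/km²) of its collection decade, with
optional block-mean aggregation of the density raster (4 km, 10 km).
Cell lookup uses half-open intervals [west, east) × [south, north), so
every interior point maps to exactly one pixel; records after the last
density decade use the latest layer. Continuous predictors are
standardized with the sample (n−1) SD, and the means/SDs are kept so
coefficients can be expressed per natural unit (°C, mm,
log persons/km²).

## Zonation

Records are projected with an Albers equal-area conic (standard
parallels 29.5°/45.5°, origin 23°N 96°W, spherical earth) so
"200 × 200 km" is metrically meaningful. The optimizer draws candidate
square cells uniformly over the projected bounding box for up to
200,000 iterations, retains candidates holding ≥ 75 records with ≥ 4
decade bins of ≥ 10 records each, and replaces overlapped cells only
when the candidate holds strictly more records than their combined
total — which makes the zoned record count non-decreasing over
iterations. Cells are free-floating (corners sampled continuously);
edge-touching cells do not conflict. An O(1) summed-area-table upper
bound rejects empty placements, so a full-scale run (50,000 points,
200,000 iterations) takes seconds. A per-cell replacement comparison is
available as an option. Ecoregion membership is a point-in-polygon
label with three regions split at 42°N into Northern/Southern
daughters; points on shared edges resolve to the lexicographically
first region name.

## The synthetic study system

The generator emulates the study inputs at reduced resolution:

- **Climate**: MAT declines with latitude (0.7 °C/degree) plus a smooth
  random field and an optional linear warming trend; MAP has an
  independent west–east gradient. One layer per year, 0.25–0.5° cells.
- **Density**: a strictly positive floor (0.01 persons/km²) plus
  exponentially decaying city kernels whose amplitudes grow
  monotonically over decades.
- **Ecoregions**: longitudinal bands with 42°N split rules (stand-in
  geometry; the real Level-I polygons are inputs, not outputs, of the
  original analysis).
- **Records**: body mass follows the temporal mixed model exactly —
  intercept 20 g; standardized effects β_MAT = β_MAP = −0.5,
  β_density = −0.15, β_decade = −0.2; females +0.6 g; fall the leanest
  season (spring/summer/winter +1.8/+0.8/+0.9 g); ecoregion SD 1.2,
  source SD 0.2 (the magnitudes reported for the real system); zone
  intercept SD 0.8 and slope SD 0.25 with correlation −0.9 on a fixed
  200-km lattice; residual SD 2 g. Head-body length follows a cube-root
  allometry with multiplicative noise chosen so the log–log fit is
  moderate (adj. R² ≈ 0.45) rather than collinear; NEON records receive
  a −4 mm length bias (live-capture lengths read short; the real bias
  magnitude is unquantified, so only its sign and detectability are
  asserted). Record density over decades follows the historical shape:
  sparse before 1945, a mid-century census pulse, a present-day survey
  pulse.
- **Contamination**: juveniles, sub-9-g masses, bad dates (missing
  month/day, 1 January, pre-1895), ambiguous sex strings, and gross
  outliers are injected at configurable rates, at most one class per
  record, and labelled in a hidden truth table.

Two deliberate design choices make the generator a sharp test target.
First, every Gaussian draw is truncated at ±2.5 SD — masses and lengths
are biologically bounded — which guarantees that clean records can
never cross the 9 g floor or the 3-SD outlier threshold under default
parameters, so audit counts have exact expectations. Second, the decade
covariate uses a *fixed* affine scaling anchored to the
temporal-analysis window (bins 6–13: mean 9.5, SD √5.25) instead of
sample standardization: otherwise the post-1945 window shift re-mixes
zone slopes into zone intercepts and attenuates the very
slope–intercept correlation the temporal model estimates.

What the generator does **not** emulate: species-distribution
structure, trap-level capture processes, elevation-adjusted climate
downscaling, spatially autocorrelated residuals (the source analysis
found none and fit none), or realistic city geography. Passing
recovery tests therefore demonstrate the correctness of the estimation
machinery under the declared model, not robustness to real-data
pathologies outside it.

## Recovery experiments and their conventions

Recovery compares estimates to truth **per natural unit**: the
generator and the analysis standardize covariates over different
samples (full simulation vs. harmonized subset), so standardized
coefficients are not directly comparable, but the model is linear in
natural units and that comparison is exact. The recovery truth zeroes
the ecoregion and source random-effect SDs: the temporal model omits
those terms by design, and with a five-level unmodelled spatial
confounder, 3-SE coverage is not a property any consistent estimator
can promise. Zone labels for recovery fits come from the generator's
fixed lattice (unambiguous truth); the stochastic zonation optimizer is
validated separately against a brute-force lattice oracle.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own working scale: the shared test bundle uses
6,000 records; the headline recovery experiment uses n = 20,000 with
40 zones; model-selection replicates run 10 seeds at n = 6,000 with
candidates spanning all subsets of {MAT, MAP, decade} (sex, season,
density retained); the null control runs 100 replicates at n = 800
with 12 zones and a decade-only temporal model; the zonation scale test
uses 50,000 points and 200,000 iterations.

## Known limitations

- Crossed random intercepts use the single-group variance-components
  trick; per-observation BLUP extraction for very large crossed designs
  is quadratic in the number of factor levels.
- The Albers projection is spherical, not ellipsoidal; cell areas are
  within ~0.3% of the GRS80 values, irrelevant at 200-km granularity.
- Wald z p-values are reported for fixed effects and labelled as such;
  model comparison should rest on AICc and weights.
- The optimizer's zonation is stochastic and seed-dependent (as in the
  original procedure); only its optimality gap and invariants are
  guaranteed, not a unique layout.
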