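# Methods

This note records the models behind `occindex`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the choices
made where the design was genuinely open.

## Weighted frequency indicators

Each indicator is an employment-share-weighted average of group-level 0–100
frequency scores, rescaled to days of a 250-day standard work-year. The
construction assumes (a) group-level scores describe every worker in the
group — within-group heterogeneity is ignored; (b) a tract's exposure
profile is determined by where its residents work occupationally, not
geographically. A tract with zero workers has no defined exposure and is
reported missing, never zero. Tracts with ≤ 20 workers (configurable) are
excluded before percentile ranking and all downstream stages, since
small-denominator weights are unstable. Missing scores abort the
computation, naming the (group, hazard) pair: silent imputation would bias
the weighted sums. When the proximity construct is assembled from its two
survey items (closeness and face-to-face frequency), the unweighted mean is
used — no weighting of the two items is established.

**Percentile convention.** Percentiles are rank-based with mean ranks for
ties. The default mapping is Hazen, (r − 0.5)/n: it is symmetric around
0.5, an all-tied column sits at 0.5, and the mean percentile is exactly 0.5,
which keeps the occupational-vs-SVI gap centered. Weibull r/(n + 1) and
inclusive r/n variants are available (`percentile_rank(..., method=...)`).

## Monte Carlo noise overexposure

The JEM supplies per-group mean and SD of the TWA-8h level in dBA; the
frequency score supplies the exposed fraction of work-days. Choices:

- **Draw distribution**: Normal on the dBA scale. dBA is already a
  logarithmic (log-energy) quantity, and the JEM reports its mean/SD
  directly on that scale.
- **Frequency adjustment** (`energy_average`, default): the annualized
  exposure of a worker exposed on a fraction f of days at level L is the
  energy average L + 10·log₁₀(f); f = 0 means never exposed. A `none` mode
  ignores frequency for sensitivity analysis.
- **Threshold**: 85 dBA (NIOSH recommended exposure limit) by default,
  configurable (e.g. 90 dBA, the OSHA permissible exposure limit under
  which many JEM measurements were taken).
- **Iterations**: 100 by default; the Monte Carlo standard error is the
  across-iteration SD divided by √iterations and shrinks as 1/√iterations.
  With SD = 0 the result is exact and iteration-invariant.
- **Streams**: each tract draws from its own RNG stream keyed by
  (seed, CRC32(tract id)), so results are independent of processing order
  and stable under subsetting.

Aggregation to coarser areal units is the employment-weighted mean of tract
prevalences.

## Spatial statistics

Global Moran's I = (n/S₀)·Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²; the bivariate version uses
unit-variance z-scores of both variables and reduces exactly to the
univariate statistic when y = x. Local values zᵢ·(Wz)ᵢ/m₂ sum to n·I on
row-standardized weights. Defaults follow common practice in areal
analysis: queen contiguity, row-standardized weights, 999 permutations,
α = 0.05, conditional permutation for the local statistics (the focal value
is held fixed; its neighborhood is redrawn from the remaining tracts).

The reported permutation p-value is two-sided — twice the smaller
pseudo-count tail, capped at 1 — because it is uniform under the null
(verified by a KS check in the tests) and detects negative (HL/LH) local
association; one-sided alternatives are available. Missing values are
dropped listwise with their edges; isolated tracts get missing local
statistics rather than zero. Per-state decomposition subsets the weights to
within-state edges and skips states with fewer than three connected tracts.

## SVI gap analysis

The gap is the mean percentile of the four headline indicators (noise
prevalence, hazardous workplace, physical proximity, disease/infection —
unweighted, no weighting being established) minus the SVI percentile. The
discordance flag uses |gap| ≥ 0.25 by default, since both over- and
under-counting are of interest; one-sided variants are provided. Density
strata are < 1,000, 1,000–10,000 and > 10,000 people per square mile
(population per square metre would be physically impossible, so the
conventional per-square-mile reading is used). High-exposure/low-SVI
enclaves are the HL quadrant of the bivariate LISA of indicator percentile
against SVI.

## Stratified prevalence-ratio models

Tract outcome prevalences are modeled by Poisson regression on
pseudo-counts (prevalence × population, log-population offset) with a
natural cubic spline in % racial/ethnic minority, fitted separately within
the high- and low-exposure strata of a median split of the paired indicator
(noise → diabetes, pollutants → asthma, disease/infection → high blood
pressure). Choices:

- **Spline df**: 4 by default and configurable (df = 3 is a reasonable
  alternative); df = 1 reduces exactly to a log-linear model. The basis is
  a natural cubic regression spline with knots at data quantiles; a df-df
  fit spans intercept + df basis functions.
- **Median split**: "high" is strictly above the median; the exact-median
  tract goes low. The strata differ by at most one tract.
- **Population proxy**: tract total workers when no population column is
  supplied. Prevalence-ratio point estimates are invariant to its scale.
- **Reference**: within-stratum PR curves are relative to 0% minority;
  the between-stratum PR at m is the ratio of modeled rates
  exp(η_high(m) − η_low(m)), which equals the planted stratum effect under
  a log-linear truth.
- **Variance**: model-based by default; a robust (HC1 sandwich) option is
  provided and is the right choice when outcome dispersion is not Poisson —
  in particular for the synthetic data, whose outcome noise is
  multiplicative log-normal, where the sandwich intervals achieve
  near-nominal coverage of the planted effect (the model-based Poisson
  intervals would be conservative there).
- **SVI adjustment**: optional linear term in SVI percentile; between-
  stratum comparisons hold SVI at its overall mean.

No spatial terms or random effects enter the spline and Poisson models; the
curves describe marginal associations, and standard errors do not account
for residual spatial autocorrelation.

## Synthetic data generator

The generator emulates the statistical regime of the national inputs at
desk scale on an R×C grid of unit-square tracts:

- **Composition**: group mixing proportions are a softmax of baseline group
  sizes plus a shared smooth "industrialness" field (weight 1.1) whose
  group loadings are the same latent factor the hazard scores share, plus
  per-group smooth fields (weight 0.5). Smooth fields are white
  noise filtered with a Gaussian kernel of width `spatial_range` (default 3
  cells) — qualitative spatial autocorrelation is all that is needed, so no
  exact Gaussian-process simulation. Worker totals are
  Poisson(`mean_workers`, default 150) allocated multinomially.
- **Scores**: the four co-varying hazards load √`hazard_corr` (default
  0.95) on a shared group factor; at the example setting 0.97 the generated
  tract-level indicators correlate pairwise above 0.9. The
  disease/infection and proximity scores take small controlled loadings
  (−0.05 and +0.15) on the composition-gradient direction, pinning their
  indicator correlations at weak/mixed-sign and moderate-positive rather
  than leaving them to random alignment.
- **JEM**: group mean TWA-8h tracks the noise score
  (74 + 0.3·(score − 50) dBA, SD uniform on 8–12 dBA), producing median
  tract overexposure prevalences near 10% under the default threshold.
- **SVI**: a noisy monotone transform of expected tract exposure achieving
  approximately the target correlation `svi_exposure_corr` (default 0.5; a
  free knob, since the real-world joint distribution is not established).
- **Outcomes**: log prevalence = intercept + slope·(% minority − ½) +
  `planted_log_pr`·1[high stratum] + log-normal noise (σ = 0.05). Each
  outcome's high stratum is the median split of its paired indicator,
  computed with the same rules the analysis applies — for asthma and high
  blood pressure from the realized weighted indicator (so the analysis
  split recovers the planted mask exactly), for diabetes from the analytic
  expected overexposure prevalence (which the Monte Carlo estimate
  approaches). Planting on any latent mask the analysis cannot reconstruct
  would contaminate the stratum contrast with misclassification bias and
  make calibration of the estimator untestable.

What the generator does **not** emulate: survey margins of error in the
employment counts, occupation-code crosswalk noise, within-group spatial
variation in JEM levels, realistic national score distributions (generated
medians sit near mid-scale rather than at the skewed values real data
show), irregular tract geometries, or missing data patterns. Passing tests
therefore demonstrate correctness and calibration of the estimators under
the assumed data-generating regime, not agreement with any national
numbers.

## Problem sizes

The test suite and the acceptance script run the pipeline at 144–2,000
tracts (up to a 40×50 grid), with 100 Monte Carlo iterations, 99–999
permutations, and 50 replicates for the coverage experiment — sizes chosen
so the complete suite runs in a couple of minutes on one CPU while leaving
the statistical checks well-powered.

## Known limitations

- Ecological design throughout: all quantities are tract-level; nothing
  supports individual-level inference.
- The Monte Carlo estimator treats workers as exchangeable within groups
  and tracts; JEM levels carry no spatial variation.
- Permutation inference on the LISA maps is per-tract with no multiplicity
  correction (none is conventional for these maps).
- The percentile convention and the Poisson pseudo-count likelihood are
  reasonable reconstructions where no single standard exists; both are
  configurable and documented above.
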