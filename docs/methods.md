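# Methods

`planktte` implements a pipeline linking the size structure of plankton
communities at two trophic levels — nano-microplankton "prey" and
non-carnivorous mesozooplankton "predators" — to a proxy for biomass trophic
transfer efficiency, and the mixed-model machinery used to relate both to
environmental conditions. This note records the models, conventions and
numerical choices, and what the synthetic tests do and do not establish.

## Morphometry

Imaging instruments (FlowCAM for prey, ZooSCAN for predators) yield the
major (M) and minor (m) axes, in µm, of the ellipse enclosing each
individual's imaged area. Only two axes are measured, so the third body axis
is assumed equal to the minor one and individual biovolume is the prolate
spheroid

    EllipVol = (π/6) · M · m²   [µm³].

This is preferred over the equivalent spherical diameter because
mesozooplankton are typically elongated; treating a copepod as a sphere of
its longest dimension overestimates its volume severalfold.

Carbon biomass is `factor · EllipVol^exponent` per trophic group (optionally
per taxon class). The shipped defaults (`factor = 1, exponent = 1`,
`shrinkage_factor = 1`) are deliberate placeholders — conversion factors and
the preservation-shrinkage correction for fixed nano-microplankton cells are
instrument- and taxon-specific and must be supplied from the literature for
real data; the package warns when the shrinkage default is in use. The
processing order is fixed and pinned by tests: carnivore filter → shrinkage
(prey only) → biomass conversion → aggregation. Shrinkage and the power law
commute only when the exponent is 1, which is why the order is part of the
contract.

Total group biomass is Σ weightᵢ·biomassᵢ (mg C m⁻³), where each measured
individual carries an abundance weight (individuals m⁻³ it represents). An
empty group is an error rather than zero, because the predator:prey ratio
downstream would be undefined.

## Size diversity

Size diversity μ is the differential entropy of the kernel-estimated density
of log individual biovolume,

    μ = −∫ p_x(x) · log p_x(x) dx,   x = log(EllipVol),

a Shannon-analogue defined on a continuous trait rather than on species
counts. The log transform stabilises the apparent variance across organisms
spanning many orders of magnitude in volume.

Estimation choices:

* **Kernel and bandwidth.** Weighted Gaussian KDE
  (`scipy.stats.gaussian_kde`); bandwidth by Silverman's Gaussian-reference
  rule on the weighted sample by default (Scott's rule and a fixed
  user-supplied bandwidth are available; the fixed mode exists for
  sensitivity analysis and for degenerate samples). The bandwidth rules use
  the effective sample size (Σw)²/Σw².
* **Integration.** Trapezoid rule on a uniform 1024-point grid extending 4
  bandwidths beyond the data range, with 0·log 0 := 0. Halving or doubling
  the grid changes μ by < 10⁻³ (guarded by a test); the grid extension keeps
  the density's integral within 10⁻³ of 1.
* **Log bases.** Natural log for both the size transform and the entropy
  (μ in nats) by default; base-10 sizes and base-2 entropy are available.
  All internal comparisons are base-consistent, so conclusions do not depend
  on the choice.
* **Weights.** Abundance weights are normalised by their sum as the very
  first step, so μ depends on *relative* contributions only: scaling all
  weights by any positive constant leaves μ unchanged (exactly so when the
  scaling is floating-point exact). This is the sense in which size
  diversity is mathematically independent of total biomass — any empirical
  diversity–biomass relationship is biological, not arithmetic.
* **Canonical ordering.** The weighted sample is sorted before estimation,
  making μ exactly invariant under permutation of the input rows.
* **Degenerate samples.** Fewer than two individuals, or all sizes
  identical without a fixed bandwidth, raise a dedicated error; with a fixed
  bandwidth an all-identical sample is a single Gaussian bump whose entropy
  is ½ln(2πeh²).

One subtlety: listing every individual twice leaves relative contributions
unchanged and therefore leaves μ *exactly* unchanged at fixed bandwidth, but
any data-driven bandwidth rule sees a doubled effective sample size and
sharpens h by 2^(−1/5), shifting μ by ~0.01. This is a property of bandwidth
selection, not of the entropy functional.

The estimator is consistent for the true differential entropy: on N(0, σ²)
samples it converges to ½ln(2πeσ²) (≈1.41894 nats at σ=1), checked at
n = 10³…5·10⁴ with shrinking tolerances, and is monotone in σ.

## Transfer metrics

* **Proxy.** log₁₀(PPBR) = log₁₀(predator biomass / prey biomass). Used as
  the trophic-transfer-efficiency proxy because turnover rates cannot be
  measured routinely; antisymmetric under exchanging the two levels.
* **Validation target.** log₁₀(PPPR), the production-rate ratio, with
  production P = g·B and the artificial-cohort growth rate
  g = ln(Wt/W0)/Δt from the mean-mass change of an incubated cohort.
  Negative rates (mass loss) are retained with a warning rather than
  truncated. The copepod-subset restriction used in field comparisons is a
  row filter on the cohort table, not a modelling step.
* **PPMR.** log₁₀ of the ratio of abundance-weighted *geometric* mean
  individual biomasses (predator over prey); the geometric mean is the
  natural average for a log-scale size variable.
* **Bootstrap.** Case resampling of samples (never of individuals within a
  sample), 1000 replicates by default, percentile 95% intervals for the
  Pearson correlation between proxy and target. An optional refit hook
  re-estimates a chosen model on every resample and reports the fraction of
  replicates in which each coefficient keeps its full-data sign. At the
  survey-like setting (true r = 0.84, n = 29) the percentile interval's
  actual coverage is slightly below nominal (a known property of percentile
  intervals for correlations at small n) but above 90%.

## Environmental covariates

"Depth-integrated" nutrients are depth-weighted mean concentrations (µM):
the trapezoid integral of concentration from the shallowest bottle to the
mixed-layer depth, divided by the span. Keeping the result on the
concentration scale (rather than an areal stock in mmol m⁻²) lets nutrient
terms enter the regressions in the same units as surface measurements. If
the MLD falls between bottles the concentration there is interpolated
linearly; a single bottle above the MLD is returned as-is with a warning.
Nutrients are log-transformed before modelling (they are right-skewed); when
zeros are present (below detection limit) the smallest positive observation
is used as the offset, logged loudly. MLD itself is an input, never
estimated here.

## Mixed models and selection

The response (log₁₀(PPBR), or a size diversity when exploring top-down /
bottom-up structure) is modelled with fixed covariate effects and a random
intercept per station, absorbing the pseudo-replication of repeated visits.

Conventions (each is a genuine choice the underlying tools leave open, fixed
here and enforced by tests):

* **Estimation.** Maximum likelihood, not REML, whenever models are compared
  by AICc — REML likelihoods are not comparable across fixed-effect
  structures. REML remains available for reporting a single model.
* **Denominator df.** Containment rule `df = n_obs − n_groups − n_slopes`:
  106 observations over 40 stations with one slope give 65; a single
  ungrouped block with no slopes gives 105. An interaction column counts as
  one slope.
* **Standard errors.** The fixed-effect covariance (X′V̂⁻¹X)⁻¹ is computed
  directly from the estimated variance components via the per-group Woodbury
  identity (robust where the random-intercept variance is estimated at the
  boundary, where the optimiser's numerical covariance can lose
  positive-definiteness), then rescaled from the ML profile denominator (n)
  to the containment df. Consequence: with one group and zero random-effect
  variance, slope t-statistics equal ordinary least squares exactly. The
  intercept in that single-group case is confounded with the group's random
  effect and is not comparable across estimators.
* **AICc.** −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = fixed effects (intercept
  included) + 2 variance components.
* **Dredge.** All-subsets selection enumerates every fixed-term subset
  respecting marginality (an interaction only enters with both main
  effects); for two mains and their interaction that is 5 admissible models
  ({}, {A}, {B}, {A,B}, {A,B,A:B}). Ties in AICc break toward fewer
  parameters, then input order; more than 20 terms are refused. p-values are
  reported for description but never drive selection.
* **Singular fits.** A random-intercept variance estimated at ≈0 is allowed
  with a warning, as is the degenerate noise-free optimum (zero residual
  variance, SEs reported as 0).

## Synthetic data

No survey data ship with the package; the generator provides the test
surface with known ground truth.

* **Communities.** Per sample and group, log-biovolumes are drawn from a
  mixture of normals (mixtures allow the bimodality that stresses the KDE);
  axes are back-computed from the drawn volume and a log-uniform aspect
  ratio M/m — [1, 1.5] for near-spherical prey, [2, 6] for elongated
  predators — so the round trip through the spheroid formula is exact to
  rounding. Defaults emulate a shelf-sea survey: 40 stations, 3 samples per
  station, 3500 prey and 2000 predator individuals measured per sample;
  default mixtures span ln-volumes ≈ 4–10 (prey, nano-micro range) and
  ≈ 14–21 (predators, mesozooplankton range). A configurable fraction of
  predators (default 0.1) is flagged carnivorous purely to exercise the
  filter; abundance weights are lognormal (median ≈ 2 ind. m⁻³).
  Environmental covariates are multivariate normal around station-level
  draws with nutrient profiles increasing linearly with depth; the
  hydrography is schematic, with no claim to match any real shelf sea.
* **Regression tables.** 106 observations spread near-evenly over 40
  stations by default, with user-specified slopes (interactions allowed),
  random-intercept SD (default 0.3) and residual SD (default 0.4) — noise
  magnitudes chosen so that single-covariate fits at survey scale give
  standard errors comparable in relative size to published shelf-sea
  mixed-model tables; slope magnitudes in the tests (e.g. −1.655) are taken
  from that same scale.

What passing synthetic tests show: the estimators recover the generating
size distributions, slopes, variance components and model structure under
the stated survey geometry. What they do not show: robustness to taxonomic
mis-sorting, instrument segmentation error, non-Gaussian covariate
dependence, or spatial autocorrelation between stations (not modelled —
random intercepts treat stations as exchangeable).

## Reproducibility

Every generator and the bootstrap take explicit seeds (NumPy `Generator`);
the pipeline derives independent per-stage streams from one master seed.
Pipeline outputs embed a SHA-256 hash of the canonical configuration, and
rerunning with the same configuration is byte-identical.

## Problem sizes used in the shipped checks

Entropy convergence uses up to 5·10⁴ draws; parameter-recovery and
model-selection checks use 100 replicates of the 106-observation / 40-station
layout; bootstrap coverage uses 200 replications × 1000 resamples at n = 29.
These sizes make the whole suite run in a couple of minutes on one core
while leaving the Monte-Carlo error well below the asserted margins.
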