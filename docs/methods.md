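# Methods

## Generative model

A cohort is n i.i.d. draws of a 2R-dimensional Gaussian vector, R regions
(default 18 cortical/subcortical labels) by two modalities (default BPND,
unitless receptor binding; CBF, mL/100 g/min). The covariance is a
"covariance pattern": sd σ_mr per cell and a correlation matrix with exactly
four parameters — exchangeable within-modality correlations ρ_w,m, a
cross-modality same-region correlation ρ_s and a cross-modality
different-region correlation ρ_d. This is the minimal structure with a
clean two-level interpretation: writing X_imr = a_im + e_imr with
participant-level modality effects a_im (var ρ_w,m on the correlation
scale, cov(a_1, a_2) = ρ_d) and regional noise e_imr, ρ_s is the *marginal*
cross-modality correlation within a region and

    ρ_c = (ρ_s − ρ_d) / sqrt((1 − ρ_w,1)(1 − ρ_w,2))

is the *conditional* correlation carried by the regional noise alone. The
identity is verified in the tests against a brute-force Schur-complement
oracle on the joint covariance of (X_1r, X_2r, a_1, a_2). Sampling uses the
Cholesky factor of the full 2R×2R covariance rather than the random-effect
representation: the pattern form stays valid for ρ_d < 0 and for
ρ_d² > ρ_w,1·ρ_w,2, where no latent-effect construction exists.

Scenario targets are stated as (marginal, conditional) pairs and solved for
(ρ_s, ρ_d) by inverting the identity; infeasible pairs are rejected by a
positive-definiteness check at the working region count.

## Default fixture

The scenario grid toggles region-specific means, region-specific variances
and the presence of cross-modality correlation: A (neither mean nor
variance region-specific; marginal/conditional 0.250/0.500), B
(region-specific means, no cross-modality correlation), C (region-specific
means, 0.250/0.500), D (region-specific variances, no correlation), E
(both region-specific, 0.135/0.057).

Parameters that matter and their defaults:

- **Mean profiles** (18 values per modality): plausible receptor-binding
  (~0.3 subcortical to ~1.25 neocortical, unitless) and perfusion values
  (~40–66 mL/100 g/min), calibrated so their across-region Pearson
  correlation is 0.672 — the empirical similarity of the two population
  maps this generator emulates. Calibration shifted the CBF profile along
  the standardized BPND profile and froze the result in the fixture.
- **Baselines** (used when a feature is not region-specific): BPND mean
  0.88, sd 0.20; CBF mean 54, sd 8 — the profile averages, so scenarios
  differ only in the toggled feature.
- **Spread vs noise**: the profile spread exceeds the standard error of a
  regional mean at n = 24 by ~11× (BPND) and ~6× (CBF), so in scenarios
  with region-specific means the across-regions estimate is driven by the
  mean profiles, attenuated only a few percent by sampling noise.
- **ρ_w = 0.5 for both modalities.** The within-modality between-region
  correlation of the source data is not published; 0.5 reflects the strong
  shared participant-level component typical of regional PET and ASL
  summaries. Most benchmark cells are insensitive to it (the scenario-A
  across-regions cells depend only on ρ_c and R; the regional-average mean
  only on the marginal), but it does set the dependence between regional
  estimates and hence strategy-2 power and the finite-sample behaviour of
  the aggregate test (see limitations).
- **SD profiles** (scenarios D/E): ~0.05 + 0.18·mean for BPND, 0.15·mean
  for CBF — variance roughly tracking signal level.

What the generator does **not** emulate: non-Gaussian tails, scanner or
session effects, missing data, spatially smooth (distance-dependent)
correlation — within-modality dependence is exchangeable, not spatial — and
any kinetic-modelling or quantification error structure. Passing benchmarks
therefore demonstrate the statistical mechanism (mean-structure confounding
of spatial correlations; correct calibration of participant-level
inference under the model), not robustness to real acquisition artefacts.

## Estimation strategies

Pearson inference follows the standard implementation (two-sided t test on
n−2 df; Fisher-z CI with variance 1/(n−3)); it is cross-checked in the
tests against R's `cor.test` to 10 digits. Degenerate r = ±1 reports p = 0
with a point CI; n < 4 or zero variance is refused. All tests are
two-sided at 0.05 with no multiplicity adjustment.

- **1.1**: Pearson across the R participant-averaged pairs, n_units = R.
- **1.2**: a seeded permutation assigns the first ⌊n/2⌋ participants to the
  first modality's cohort and the rest to the second (splits are
  reproducible given the seed); in simulations the second cohort is an
  independently simulated dataset of the same n, matching the independent-
  cohorts design the strategy mimics.
- **2**: per-region Pearson estimates; the summary point estimate is the
  arithmetic mean of the r values, while the test and CI are built on the
  Fisher-z scale — mean z with variance 1ᵀΣ_z1/R², Σ_z = C/(n−3), C the
  sample correlation matrix of the per-participant influence values
  ψ_i = x̃ᵢỹᵢ − (r/2)(x̃ᵢ² + ỹᵢ²). The CI is mapped back by tanh, so it is
  centred on tanh(z̄), not on the mean of r values: a small deliberate
  inconsistency in exchange for a point estimate that matches the plain
  average of regional correlations. Since tanh is monotone, scoring CI
  coverage on the z scale or after back-transformation is identical.
- **3**: maximum likelihood for the covariance-pattern Gaussian. In a
  balanced design the ML means equal the sample mean vector for any
  covariance, so the likelihood is concentrated to covariance parameters
  only: −2ℓ/n = 2R·log 2π + log|Σ| + tr(Σ⁻¹S) with S the 1/n-denominator
  sample covariance; fit cost is therefore independent of n. Parameters are
  optimized as log σ and atanh ρ (L-BFGS-B, moment-based start plus a
  zero-correlation start, Nelder-Mead polish on line-search failure);
  non-positive-definite proposals get a large penalty. ML rather than REML
  keeps the log-likelihood exactly comparable to the direct density oracle;
  at the benchmark sample sizes the ML/REML difference is negligible for
  the correlation parameters. Wald inference for the marginal correlation
  is read off the atanh-scale parameter with the observed-information
  (numeric Hessian) variance; the conditional correlation gets a
  delta-method interval, also on the atanh scale so CIs stay inside
  (−1, 1). The variance structure is by-modality (2 sd parameters) by
  default — the simulation-study configuration, deliberately mis-specified
  under scenarios D/E — or by region × modality (2R parameters) by flag.

## Simulation harness

Each strategy is scored against its own estimand: conditional correlation
for 1.1/1.2, marginal for 2/3 (recorded in the summary as `truth`).
Metrics: mean estimate, relative bias 100·(mean − truth)/truth (undefined
at truth 0), CI coverage, and rejection rate at p < 0.05 (type-1 error
when truth = 0, power otherwise), each with binomial or empirical
Monte-Carlo SEs. Replicate k runs on an independent substream spawned from
the master seed, so results are reproducible per replicate and invariant
to the strategy subset; strategy 1.2's second cohort uses a further
substream. Non-converged mixed-model fits are excluded from strategy-3
summaries only, with the count reported.

Problem sizes: the benchmark suite and the acceptance script use 2000
replicates for the closed-form strategies (proportion MC SE ≤ 0.011) and
200–300 for mixed-model cells, the package's desk-scale defaults; 10,000
replicates reproduce survey-grade Monte-Carlo error.

## Numerical choices and degenerate inputs

- Fisher CI requires n ≥ 4; the subsampling experiment therefore bounds
  k ≥ 2 for estimation but inference quantiles are meaningful from k = 4.
- `aggregate_regional` with R = 1 reduces exactly to the Fisher-z interval
  of the single regional estimate (the influence correlation matrix is 1).
- Results CSVs are written with %.17g floats and read back with
  round-trip parsing, so numeric round-trips are exact.
- Seeds: integer seeds, `SeedSequence` or `Generator` objects are accepted
  everywhere; identical inputs give byte-identical simulated tables.

## Known limitations

- The aggregate (strategy-2) test estimates an 18×18 correlation matrix
  from n = 24 influence vectors; the resulting variance estimate is noisy
  and the test runs slightly hot in small samples under our defaults
  (empirical type-1 ≈ 0.06 at n = 24 rather than 0.05; it approaches the
  nominal level as n grows). A shrinkage estimate of the influence
  correlation would temper this at the cost of departing from the plain
  method the package documents.
- The exchangeable within-modality structure cannot express spatially
  graded dependence; with real data the mixed model's four-parameter
  correlation is a working structure, not an anatomical claim.
- The mixed model's Wald/delta intervals are asymptotic; at n ≪ R² their
  coverage dips a few points below nominal (visible in the n = 24
  mixed-model cell, coverage ≈ 0.92–0.94).
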