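# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limits of what the tests demonstrate.

## The analysis chain

The package estimates climate-driven range change for a presence-only
species (or pooled clade) in five stages: build a weighted
presence/pseudo-absence training table; fit four habitat-suitability models
and combine them into an AUC-weighted ensemble; binarise the ensemble at the
minimal-predicted-area (MPA) threshold; project the binary range onto
perturbed future climates under two dispersal extremes; and convert losses
into threat categories and fragmentation metrics. Each stage is a pure
function of its inputs and a seed derived from the master seed and the stage
name, so whole runs are reproducible bit-for-bit.

## Constituent models

All four models share the contract `fit(X, y, sample_weight)` /
`predict(X) -> [0, 1]` and store their predictor standardisation constants,
so projections onto future climates reuse the training scale.

* **GLM.** Weighted binomial regression with logit link on candidate terms
  {x_j, x_j²} over standardised predictors. Model search starts from the
  full model and applies single add/drop moves minimising AIC, ties
  favouring the smaller model; the selected AIC is therefore never above the
  full model's. Statsmodels provides the IRLS fit; weights enter as
  frequency weights.
* **GBM.** Stochastic gradient-boosted classification trees (scikit-learn),
  Bernoulli deviance, defaults 2500 trees, learning rate 0.001, bag
  fraction 0.5, depth 3, seeded subsampling.
* **SRE (BIOCLIM).** Rectangular envelope of the presence values. The
  configured `trim_quantile` is the *total* trimmed mass, split across both
  tails (default 0.05 → 2.5% per tail); bounds use linear-interpolation
  quantiles, fixed and documented because envelope bounds are sensitive to
  the quantile rule. Prediction is the conjunction of per-predictor bounds,
  hence binary.
* **MaxEnt-like.** L1-penalised logistic regression over an expanded
  feature basis: linear, quadratic, all pairwise products, and
  forward/reverse hinge features at five per-predictor quantile knots
  (threshold/step features optional, off by default). This penalised
  presence–background logistic formulation is the standard equivalent of
  the maximum-entropy estimator and keeps the package self-contained; the
  regularisation multiplier defaults to 1.0 and the intercept is effectively
  unpenalised (large `intercept_scaling`), mirroring the free normaliser of
  the entropy formulation. The solver is capped at 200 iterations.

Case weights balance the classes: presences weigh 1, absences
n_presences/n_absences, so total class weights are equal. Evaluation metrics
(AUC, TSS) are computed unweighted on held-out rows — the weights are a
fitting device, not part of the reporting convention.

## Evaluation and ensemble

Ten stratified 75/25 split-sample replicates; all algorithms see the same
split within a replicate. AUC uses the Mann–Whitney formulation (ties count
half); TSS scans all distinct scores as thresholds with prediction
"suitable" iff score ≥ threshold and returns the smallest maximising
threshold. Ensemble weights are proportional to mean replicate AUC, members
are refit on 100% of the data afterwards (full-model consensus practice),
and no skill cutoff gates membership. Consensus AUC/TSS can be computed
either on held-out rows or by resubstitution; the package reports replicate
(held-out) metrics by default.

## Projection and risk rules

* **MPA threshold.** Minimum ensemble suitability over occurrence cells; no
  occurrence is discarded as marginal, so every occurrence cell is suitable
  at the threshold. The threshold is computed once from the current-climate
  ensemble and reused unchanged for futures.
* **Binarisation.** Suitable iff suitability ≥ threshold (ties suitable);
  nodata is never suitable.
* **Footprint mask.** Cells with human-footprint index strictly greater
  than 50 are removed from current and future ranges alike (the mask is
  static; future land-use change is out of scope).
* **Dispersal.** "none" intersects the future range with the current one;
  "unlimited" takes the future range as projected.
* **Range change.** loss = |current∖future|/|current|, gain =
  |future∖current|/|current|, stable = |current∩future|/|current| (×100).
  Statistics are computed per GCM and then summarised as mean and SD across
  GCMs; cell counts stand in for areas (at ~1 km cells the conversion is a
  constant factor within a study region). Consensus maps additionally
  average the per-GCM suitability rasters.
* **Threat levels.** 1 iff loss = 100%, 2 iff 80 ≤ loss < 100, 3 iff
  50 ≤ loss < 80, 4 iff 30 ≤ loss < 50, else 0 ("below assessment
  thresholds"; no category is defined under 30% loss). Boundaries follow
  the quoted inequalities exactly.
* **Landscape metrics.** Patches are rook-connected components (queen
  optional). AI = 100·g/g_max with g the number of shared edges between
  suitable cells and g_max the compact-arrangement maximum for the class
  area (n = ⌊√A⌋, m = A − n²: 2n(n−1), +2m−1 if 0 < m ≤ n, +2m−2 if m > n);
  undefined for a single-cell class. SI = A²/Σaᵢ² with A the valid
  landscape cell count by default (`si_denominator="class"` uses the class
  area instead, for the reading in which only the class is subdivided).

## The synthetic study system

The generator emulates the *structure* of the real inputs, not their
physics:

* **Climate layers** are unit-variance Gaussian random fields (white noise
  smoothed with a Gaussian kernel of width `autocorr_range_cells`, default
  10 cells on a 100×100 grid) plus a north–south gradient (strength 0.7),
  named after the six bioclim variables such an analysis typically retains.
  Collinear structure is built in: each of `collinear_pairs` (default 2)
  extra layers is a base layer plus 10% noise, giving |r| ≈ 0.99 pairs for
  the screening stage to remove.
* **Terrain** is a smooth ridge field (folded Gaussian field) scaled to a
  3000 m relief; the **footprint** layer maps the rank of a smooth latent
  field to 0–100 so that exactly the configured fraction of cells (default
  0.1) exceeds the developed cutoff of 50, in spatial clusters.
* **The virtual species** has suitability logistic(c + Σ lin·x + quad·x²)
  with quad ≤ 0 (unimodal niche); the intercept is calibrated by bisection
  so mean suitability hits the prevalence target (default 0.15, a
  range-restricted species) within 0.02. The default coefficients
  (lin = 8, quad = −16 on bio1) give a strongly climate-determined,
  near-binary suitability surface: occurrences then carry enough signal
  that held-out AUC/TSS clear the conventional 0.8/0.6 bars, and range
  estimates are insensitive to the exact threshold — the regime the
  original study reports for its models. Weaker determinism (e.g. lin = 2)
  produces realistic but noisy species for which those bars are *not*
  reached; tests that assert the bars use the sharp default.
* **Occurrences** are sampled without replacement, one per cell, with
  probability proportional to suitability — mimicking thinned field
  records.
* **Futures** shift named layers additively (per-GCM smooth noise fields
  optional). A base layer's collinear copies are shifted coherently with
  it: correlated climate variables move together in any physically
  consistent scenario, and shifting only one would let the screening stage
  retain the unshifted copy and hide the change from the projection.
  Scenario severity grows with period and emissions pathway
  (RCP4.5/2050 → RCP8.5/2070 factors 1.0, 1.6, 1.8, 2.6 on a base shift of
  0.12 layer-standard-deviations), so projected contraction increases over
  time and severity by construction. The base shift is calibrated to the
  default species' niche width so the severity ladder spans moderate to
  severe (not total) range loss; a species with a broader niche needs a
  proportionally larger shift for the same effect.

### Ground truth for range loss

The virtual species' "true range" under a climate is defined operationally,
by the same rule the pipeline applies to its estimate: the MPA rule on the
*true* suitability field. The truth cutoff is the minimum true suitability
over the sampled occurrence cells, held fixed between the current and the
perturbed climate; the true no-dispersal loss is the fraction of
current-range cells leaving the range under the perturbation.
`calibrate_shift_for_loss` bisects the shift magnitude to construct futures
with prescribed true losses (e.g. 25/50/80%). Defining truth at an
arbitrary fixed level such as 0.5 instead would build in a systematic
mismatch: MPA-thresholded estimates are deliberately liberal (every
occurrence cell counts as occupied), so they track the occupancy-defined
range, not a mid-suitability contour.

## Problem sizes used in the tests

Skill bars are checked at the study's design size (300 presences, 10,000
pseudo-absences, 100×100 grid, 10 replicates). Truth-recovery runs use
5,000 pseudo-absences and 3 evaluation replicates per seed across 5 seeds —
the replicate count only sets ensemble weights, and background size beyond
a few thousand points changes the fitted surfaces negligibly at this grid
size. The structural-invariant checks run on a 45×45 grid.

## What passing tests do and do not show

The synthetic system verifies the *machinery*: screening removes built-in
collinearity, models recover a known niche, the ensemble's loss estimates
track constructed true losses within ~10 percentage points, rules and
metrics match independent oracles. It does not validate transfer to real
data: real climates have cross-variable covariance structure, non-additive
futures, observation bias in occurrences, and species that violate the
equilibrium assumption. The generator's perturbations are phenomenological
(additive shifts + smooth noise), so GCM disagreement is emulated only as
spatial noise, not as structured physics.

## Known limitations

* MPA thresholding is an extreme statistic (a minimum over occurrences);
  with diffuse suitability surfaces the predicted range can be much larger
  than any fixed-contour range, and single marginal occurrences move the
  threshold. This is a property of the method, preserved deliberately.
* The GLM stepwise search refits at every candidate move; for tens of
  predictors it becomes the slowest stage.
* No spatial cross-validation, no partial-dispersal kernels, no temporal
  stepping between periods, no EOO computation — out of scope by design.
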