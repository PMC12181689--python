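# Methods

## Scope and model

The package implements the standard presence-only workflow used to evaluate
a reintroduction against a modelled potential distribution: screen and
prepare environmental predictors, fit an ensemble of MaxEnt models, select
the best by held-out AUC, average their suitability surfaces, delineate the
occupancy area at each model's kappa-maximising threshold, compare it with
observed records, and re-project the selected models onto future climates.

MaxEnt is treated as what it is mathematically: maximum-likelihood
estimation of a Gibbs distribution `q_λ(x) = exp(λ·f(x))/Z_λ` over the
background sample, with an L1 penalty `β_j = c_kind · s_j/√m` (presence
count `m`, presence-sample feature sd `s_j`, per-class multipliers
`c = 1` for linear/quadratic/product, `0.5` for hinge, `1` for threshold,
all scaled by a global `beta_multiplier`, default 1.0). Feature classes are
chosen by presence count: below 80 records linear+quadratic+hinge, from 80
up all five classes; hinge/threshold knots sit at equally spaced training
quantiles (8 per variable by default). Presences are **not** added to the
background (both conventions exist; a switch is deliberate future work, the
background here is a pure availability sample).

### Optimiser

The penalised likelihood is concave; weights are fitted with monotone
accelerated proximal gradient descent (MFISTA): backtracking on the smooth
majorisation, soft-thresholding for the penalty, and the accepted iterate
is always the best-so-far, so the penalised objective is non-decreasing at
every iteration — a property the tests assert directly. Convergence is an
objective change below `tol = 1e-6` (default) within `max_iter = 500`
iterations; non-convergence flags the model but does not abort the
ensemble. Plain (non-accelerated) proximal gradient was measurably too slow
to reach `1e-6` in 500 iterations on realistic feature matrices.

### Output transform

Map-scale suitability is cloglog, `p = 1 − exp(−e^H q)`, with `H` the
entropy of the fitted distribution over the training background. It is a
strictly monotone transform of `q`, so AUC and rank-based comparisons are
identical between scales.

### Random clamping and per-run diversity

The ensemble's run-to-run variation has two seeded sources: (i) clamp
bounds drawn per variable from quantile windows of the training background
(lower bound from the [0, 0.05] quantile range, upper from [0.95, 1.0]);
projection-time values outside the bounds are held at the bound; (ii) a
fresh background subsample per run. Both are derived from the run seed,
itself spawned from the master seed. The clamping policy is isolated in
`random_clamp_spec` so an alternative reading of "random clamping" can be
swapped in without touching the ensemble.

## Evaluation and selection

AUC is the Mann–Whitney rank estimator (ties count ½). Kappa is scanned on
a 0.01-step threshold grid (0.01–0.99); ties break to the lowest threshold.
Kappa, Type I (background false-positive rate), Type II (presence
false-negative rate) and PPP are computed from test presences vs test
background scored at their own locations — an all-cell confusion matrix is
not possible without absences. Selection keeps the `k` best runs by test
AUC (ties to the lower run index); the ensemble surface is their cellwise
arithmetic mean.

## Occupancy areas and scenarios

Each selected model is binarised at its own frozen t* (probability ≥ t* =
presence); the union (cellwise OR) is the global AMPO. Areas are planar:
positive cells × cell area, no slope correction. Polygons trace
rook-connected (4-neighbour) components with vertices at cell corners —
diagonal-only contact does not merge regions. Record overlap reports the
percentage of on-land records inside the AMPO and the percentage with mean
surface probability *strictly above* each cutoff (defaults 0.65 and 0.5);
off-grid or off-land records are excluded from denominators and tallied.

Future projection re-applies each selected model — training normalisers,
clamp bounds, t* all frozen — to every scenario stack (3 SSPs × 5 GCMs by
default) with land cover and topographic layers held constant; only climate
layers change. Change statistics are mean ± sample sd (ddof = 1) of the
percentage area change per SSP across GCMs, per GCM across SSPs, and
overall.

## Predictor preparation

* **Resampling** is cell-centre bilinear interpolation with clamped-edge
  extension; nodata propagates if any of the four contributing source cells
  is nodata. Bilinear weights are convex, so fractional layers stay in
  [0, 1] and sums stay ≤ 1 after resampling.
* **Terrain** uses Horn's 3×3 weighted differences for slope (degrees) and
  aspect (degrees clockwise from north, pointing downslope); roughness is
  the 3×3 max−min. Border cells and windows touching nodata are nodata.
  Aspect on flat cells is nodata, not 0 — 0 would alias "north". Grids
  declared geographic via their CRS id are rejected; project first.
* **Land cover** expands categorical codes to six plant-functional-type
  fractions (tree, shrub, crop, grass, urban, bare) through a crosswalk
  table; per cell the fractions sum to ≤ 1, the residual being water/other.
* **Collinearity screening** first drops the member of the highest-|r| pair
  with the larger mean |r| until all pairwise |r| ≤ 0.7, then drops the
  max-VIF variable until all VIF ≤ 10 (both conventional SDM defaults,
  overridable). Every drop is logged with its trigger value. The screen is
  a diagnostic: the fitted predictor list is a config choice, defaulting to
  the nine-variable set (four climate, tree/grass/crop fractions, slope,
  aspect; elevation and roughness are computed but excluded by default).
* **Occurrence filtering**: drop exact duplicate coordinates, drop points
  off the land mask, then keep one record per cell per source; all removals
  are tallied by reason.
* **Mantel correlogram**: per distance class, the statistic is the
  sign-flipped Pearson correlation between the pair-membership indicator
  and the environmental distance, so r > 0 means nearby points are
  environmentally more similar than average. One-sided p-values use
  label permutations with the +1 correction,
  `p = (#(r_perm ≥ r_obs)+1)/(n_perm+1)`. Classes with fewer than two pairs
  are flagged, not errors. The gate only warns (default |r| cutoff 0.15
  with p < 0.05); it never thins the data.

## The synthetic island

The generator emulates the structure of the real inputs, not their values:

* **DEM** — a radial cone (peak 1500 m, cone radius 0.42 of the short grid
  side, leaving a sea margin) plus ridged noise (crests along the zero
  contours of a smoothed Gaussian field, amplitude 10 m per unit of
  `noise_sd`); cells at or below sea level are nodata and land is reduced
  to its largest 4-connected component. `noise_sd = 0` gives an exact cone.
* **Climate layers** — `a_k + b_k·elevation` plus spatially correlated
  noise (white noise, uniform-kernel smoothed over `smoothing_radius = 3`
  cells, variance restored after smoothing). Gradients alternate in sign
  and are sized so each layer spans roughly ±20 units over the relief,
  making one `noise_sd` (default 1.0, i.e. ~5% of the signal span)
  comparable across layers. Even-indexed layers (positive gradient) play
  the "temperature-like" role in scenarios, the others "precipitation-like".
* **Land cover** — the DEM aggregated 3×3 and banded into six classes
  (coastal bare, settlement, cropland, grassland, scrub, summit forest),
  mapped to PFT fractions by a fixed crosswalk.
* **Ground truth** — logistic-linear suitability in the standardised
  climate layers. The benchmark coefficients (−3, 3, −2, 4, 1.6) define a
  concentrated habitat-specialist niche whose presence-vs-background
  discriminability (AUC of the truth surface itself) is ≈ 0.81; weaker,
  diffuse effect sizes cap every model's attainable AUC below the 0.75
  selection floor the ensemble is expected to clear, so the benchmark is
  deliberately a specialist, as a reintroduced forest pigeon is.
* **Presences** — cells drawn with probability ∝ suitability (with
  replacement, then deduplicated to one record per cell; both counts
  recorded), placed at cell centres so the presence→cell mapping is exact.
  500 presences by default.
* **Future scenarios** — deterministic shifts per SSP × GCM: additive
  warming on temperature-like layers, multiplicative drying on
  precipitation-like ones, scaled by SSP severity (1.0 / 2.2 / 3.0) and GCM
  sensitivity (IPSL 1.8, UKESM1 1.5, MPI 1.0, MRI 0.7, GFDL 0.35), so the
  high-sensitivity model is the most adverse and scenario divergence is
  exact and testable. An optional seeded noise term exists but defaults
  to 0.

What the island does **not** emulate: real Canarian climatology or any
real bioclim values, anisotropic orography, coastlines with multiple
landmasses, land-cover change over time, observation bias in the records
(presences are an unbiased draw from the truth). Passing tests therefore
demonstrate that the *pipeline* recovers a known signal under clean
conditions — not that any particular real-world dataset would behave as
well.

## Benchmark sizes and defaults

The shipped benchmark runs the default island (120×120 cells at 100 m,
~7600 land cells, 500 presences) with a 2000-point background (1600/400
split, matching the 80/20 floor rule used for the published 10,000-point
background), 20 ensemble runs with 5 selected, and an 8000-point cap on the
per-run background subsample. These sizes keep a full run around ten
seconds while leaving every statistic stable across seeds (mean selected
AUC 0.78–0.86, truth Spearman ρ 0.96–0.98 over seeds 1/3/7/42). Full-scale
settings (10,000 background, 100 runs, 10 selected) are plain config
values.

Seeding: one master seed is split into fixed-purpose channels (island,
split, background, ensemble, mantel) via `SeedSequence`; each ensemble run
spawns its own child seed. Reruns with the same config and seed are
bit-identical end to end, which the run manifest digests.

## Numerical choices and degenerate inputs

* Feature scaling clips to [0, 1] at projection time; clamping is applied
  before feature expansion.
* Constant predictors keep a constant linear column but their nonlinear
  features are suppressed (warned); their β floor (`s_j` floored at 1e-3)
  keeps them penalised.
* Kappa with chance agreement 1 (all predictions one class on both margins)
  is defined as 0.
* `binarize` keeps nodata; `union_ampo` treats a cell as nodata only where
  every member is nodata.
* Presence sampling rejects requests for more deduplicated points than
  positive-suitability cells; replacement draws without dedup have no cap.
* The Mantel statistic is NaN for classes whose indicator or environmental
  distances are constant.

## Known limitations

* Kappa and the other threshold metrics are point-vs-background, not
  cell-census, quantities; with presence-only data this is the only option
  and it biases PPP interpretation toward the background sample.
* The AUC of any model is bounded above by the discriminability of the
  generating truth; comparisons across generator configs must account for
  that ceiling.
* Polygon output is plain WKT without CRS metadata (the CRS id travels in
  the raster sidecars and the manifest).
* The CLI exposes `simulate` and `run`; the intermediate stages are library
  calls, which is how the pipeline is meant to be composed in analyses.
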