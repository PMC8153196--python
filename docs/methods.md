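# Methods

## Model and estimation

`maxenm` fits a presence-background maximum-entropy model: the fitted
object is a Gibbs density over the background cells of the accessible
area, `raw(x) = exp(β·f(x))/Z`, with features `f` built from the
environmental variables after min-max scaling to [0, 1] (scaling frozen on
the calibration data, presences plus background). Feature classes follow
the MaxEnt convention:

* **L** — the scaled variable; **Q** — its square; **P** — pairwise
  products;
* **T** — step indicators `1(s > k)` at 10 knots evenly spaced inside
  (0, 1);
* **H** — forward hinges `max(0, (s−k)/(1−k))` at 20 knots `k = j/20`,
  j = 0..19, and reverse hinges `max(0, (k−s)/k)` at `k = j/20`,
  j = 1..20.

Knots are evenly spaced on the scaled range rather than at sample
quantiles: the basis is then deterministic and independent of the
background sample, which keeps candidate fits exactly reproducible under
background resampling. Column order is class-major (L, Q, P, T, H),
variables in input order, knots ascending. A constant variable yields an
all-zero scaled column and is flagged, not an error.

β minimizes the convex L1-regularized objective

    J(β) = −(1/m) Σ_i β·f(x_i) + log Σ_b e^{β·f(b)} − log N_b + Σ_j λ_j|β_j|

Per-feature penalties are `λ_j = RM · β_class(m) · s_j/√m`, where `s_j` is
the feature's standard deviation over the m presences, floored at `1/√m`,
and `β_class(m)` is linearly interpolated from the published per-class
tables (linear/quadratic/product: 1.0 at m = 10, 0.2 at 30, 0.05 at 100;
threshold: 2.0 at 10, 1.0 at 100; hinge: 0.5 at any m), clamped at the
table ends. The whole penalty vector scales linearly with the global
regularization multiplier RM.

**Optimizer.** FISTA — accelerated proximal gradient with soft
thresholding for the L1 term — with backtracking line search on the
smooth part, adaptive restart when the objective rises, and a step size
allowed to grow again after each accepted step. Stopping is dual: KKT
stationarity residual below 5·10⁻⁵ (checked every 10 iterations), or the
best objective improving by less than 10⁻⁸ over a patience window, with a
budget of 5,000 iterations. A fit that exhausts the budget with a KKT
residual still above 10⁻³ raises a `ConvergenceError` carrying the
objective trace; the grid runner catches it, flags that candidate
unrankable and continues, so one pathological candidate cannot discard
the rest of the table. Coefficients below 10⁻¹² in magnitude are zeroed
after convergence so the AICc parameter count is meaningful.

**Outputs.** `raw` sums to 1 over the calibration background by
construction (log Z is stored). The logistic output is
`e^H·raw/(1 + e^H·raw)` with H the entropy of the fitted density — the
MaxEnt 3.3.3 form, in which a cell whose raw density equals `e^{−H}`
(a "typical" cell) scores exactly 0.5. Transfer predictions clamp each
variable to its calibration range (the min/max over the accessible-area
cells) before feature expansion unless clamping is disabled.

## Occurrence handling

* Uncertainty filter: records with reported positional uncertainty
  strictly greater than 10,000 m are removed; records with *missing*
  uncertainty are also removed (logged separately).
* Range filter: point-in-polygon against a user polygon (boundary
  inclusive); generalizes manual curation of out-of-range records.
* Thinning: seeded random-order greedy rarefaction — records are visited
  in a shuffled order and kept iff farther than the cutoff (default
  50 km great-circle) from everything kept so far. The result is maximal
  (no removed record could be re-added) and idempotent. Exact coordinate
  duplicates are removed first. Exact maximum-cardinality thinning is
  NP-hard and unnecessary for rarefaction.
* Split: seeded 50/50 partition into calibration and evaluation halves
  (sizes differ by at most one). Thinning precedes the split, as the
  protocol's ordering implies.
* Accessible area **M**: union of discs of 7 degrees of arc (great-circle
  measure, not a bounding box) around the occurrences, intersected with
  the non-missing stack cells; per-variable min/max over M become the
  clamping bounds. Distances use the WGS84 mean-radius sphere
  (6371.0088 km).
* Background: all cells of M when ≤ 10,000, otherwise a seeded uniform
  sample of 10,000 (configurable). Presence cells are part of the
  background — background, not pseudo-absence, semantics.

## Candidate grid and selection

The grid crosses five feature combinations {L, LQ, LQP, LQPT, LQPTH},
19 RM values (0.1–1 by 0.1, 1–6 by 1, 8–10 by 2, 10–20 by 5) and the
variable sets produced by the jackknife (three sets with the default
four steps), giving 285 candidates. Enumeration order is canonical and
per-candidate randomness is keyed by a CRC of the candidate id, so
results are independent of iteration order; feature matrices are cached
per variable set × combo.

**Jackknife variable selection.** Each step fits a reference model
(linear + quadratic, RM = 1) on the current variables and measures each
variable's gain when used alone and the regularized training-gain drop
when it is withheld. The removal score is `gain_alone + max(drop, 0)`:
a variable is worth keeping if it carries signal on its own *or*
contributes unique signal. The drop term alone cannot separate collinear
proxies of an informative layer (their unique contribution is ≈ 0) from
spatially autocorrelated noise (which acquires small spurious gain from
clustered presences), and measured on the default virtual species ranks
noise above proxies; the combined score separates the three groups. The
lowest-scoring quartile (at least one variable) is removed per step; an
a-priori exclusion list (by default the four mixed
temperature/precipitation layers) is applied before step 1.

**Partial ROC.** The ROC curve is traced over landscape-suitability
thresholds with x = fraction of the landscape predicted present and
y = sensitivity of the evaluation points. The integration band is fixed
once per dataset — the thresholds at which the full evaluation set
attains sensitivity ≥ 1 − E (E = 5 %) — and each of the 500 iterations
resamples half the evaluation points with replacement, reporting the
ratio of the resampled partial area to the diagonal (random-expectation)
partial area over that same band. p is the fraction of iterations with
ratio ≤ 1. Re-choosing the band inside every resample conditions on
resampling noise and inflates the ratio (measured null rejection 0.47 at
p ≤ 0.1 with 50 evaluation points); with the fixed band the null
rejection is 0.10–0.16 for 100+ evaluation points. The bootstrap-ratio
construction remains anti-conservative for small evaluation sets — an
inherent property, documented rather than hidden; the type-I property
suite uses 100-point evaluation sets.

**Omission.** Threshold = the E-quantile (E = 5 %) of calibration-point
suitabilities; the rate is the fraction of evaluation points strictly
below it.

**AICc.** `2k − 2·lnL + 2k(k+1)/(n−k−1)` with k = nonzero coefficients,
n = calibration presences, and lnL the sum of log raw values at the
presences after renormalizing raw to sum to 1 over the background.
Candidates with n ≤ k + 1 are flagged unrankable.

**Selection.** Filters in protocol order: remove p > 0.1, then omission
> 0.1, then select survivors within 2 AICc units of the survivor
minimum. The `delta_aicc` column of the exported table is measured
against the *global* minimum so it is nonnegative for every row; the
selection rule itself uses the survivor minimum. Ties at the minimum are
all selected; the ensemble is built on the lowest-k (most parsimonious)
selected candidate. Zero survivors yields an empty selection, not an
error.

**Bootstrap ensemble.** The chosen configuration is refit on 10
with-replacement resamples of the calibration presences (feature scaling
refrozen per resample); the cellwise median is the headline suitability
and max − min the uncertainty surface.

## Transfer, MOP, agreement

Transfer applies every replicate to the target stack with clamping and
takes the cellwise median and range. MOP standardizes variables by the
calibration mean/sd, computes each target cell's mean Euclidean distance
to its nearest 10 % of calibration cells (exact k-NN), and rescales to
similarity `1 − d/d_max`; the strict-extrapolation mask is true where any
raw variable leaves the calibration [min, max]. Change maps binarize
suitability at the same E = 5 % calibration-quantile threshold used for
omission (re-used for consistency; configurable) and code each cell by
GCM agreement: for presently unsuitable cells, 1–4 = number of GCMs
predicting gain; for presently suitable cells, 5–8 = 4 + number
predicting loss; 9 = every GCM agrees with the present state. A second
map counts, per cell, the GCMs whose MOP flags strict extrapolation.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not real bioclimate. Layers are Gaussian-smoothed white noise
(wrap-mode smoothing keeps variance stationary), standardized and mixed
through the Cholesky factor of a target correlation matrix, on a
0.1-degree geographic lattice — so degree-based buffering and km-based
thinning are both exercised. The virtual species' truth is an
inverse-logit of linear and quadratic terms in the standardized layers;
occurrences are cell draws proportional to truth, jittered by a Gaussian
of 2,000 m, each with a uniform reported uncertainty on [10, 15,000] m so
the uncertainty filter has work to do. Future stacks add
`intensity · (Δ_mean + ε_GCM)` per layer, ε drawn once per GCM, with two
labelled intensities (1× "low", 2× "high") across four pseudo-GCMs.

The default fixture has 8 layers: BIO_1 linear (+2.5), BIO_2 quadratic
(−2.0), BIO_3/BIO_4 decoys correlated 0.9/0.85 with BIO_1 (one-factor
structure), BIO_5–BIO_8 independent noise — two signal carriers, two
correlated proxies, four distractors, which is what variable selection
has to untangle in real bioclimatic stacks. What the generator does *not*
emulate: real BIO-variable semantics and seasonality structure, sampling
bias (an optional hook exists conceptually but the default is unbiased;
museum data are not), coastlines/irregular nodata geometry, and
resolution mixing between calibration and projection rasters (the
projection stage requires co-registered inputs). Passing tests therefore
demonstrate the pipeline's statistical machinery, not fitness of any
particular real-world prediction.

## Problem sizes

The test and acceptance studies run at desk scale, chosen as study
conditions for the virtual species: 60×60-cell grids (≈ 6°×6°),
250 presence draws, 20-km rarefaction (the grid spans only ≈ 660 km, so
the protocol's 50-km spacing would leave too few records to exercise
selection), 3-degree accessible-area buffer, a 2,000-cell background cap
for grid calibration, 20 seeded replications for the recovery study and
200 seeded datasets for the null study of the partial-ROC test. The
full-protocol constants (50 km, 7°, 10,000 background, 10 replicates,
285-candidate grid) remain the defaults of `PipelineConfig`.

## Known limitations

* Active sets of L1 paths are not monotone in the penalty in general:
  at tight tolerance the exact optimum can gain a feature as RM grows
  (observed between RM 0.7 and 0.8 on two fixtures). The
  complexity-control property (nonzero count non-increasing in RM) is
  asserted on a designated fixture where it holds exactly.
* The bootstrap AUC-ratio p-value is anti-conservative for small
  evaluation sets even with the fixed band (see above).
* The optimizer reproduces MaxEnt's objective and defaults, not its
  sequential-update algorithm; coefficients need not match MaxEnt 3.3.3
  run-for-run, though the optimum of the shared objective does.
* No categorical features, sample-bias grids, or dispersal/land-use
  modelling; agreement maps assume co-registered rasters and leave
  resampling to the user-facing pipeline configuration.
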