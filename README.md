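# maxenm

Maximum-entropy ecological niche modelling for presence-only occurrence
data, built as a single reproducible pipeline: occurrence cleaning and
spatial rarefaction, candidate-model calibration over feature classes ×
regularization × variable sets, partial-ROC / omission / AICc model
selection, bootstrap ensembles, geographic transfer under present and
future climates, and MOP extrapolation analysis.

The package is aimed at distribution modelling of disease vectors (ticks,
mosquitoes) and other taxa for which only georeferenced presence records
exist — the setting where MaxEnt-style presence-background estimation is
the field standard — and at methodologists who need a fully scripted,
seedable version of that workflow to validate against virtual species with
a known truth.

## The model

Given presence sites \(x_1..x_m\) and background cells \(b_1..b_N\) drawn
from the accessible area **M**, the model is the Gibbs density over
background cells

    raw(x) = exp(β·f(x)) / Z,      Z = Σ_b exp(β·f(b))

where `f` are feature transformations of the environmental variables
(linear, quadratic, product, threshold, hinge — the classic MaxEnt
classes), and β minimizes the L1-regularized objective

    J(β) = −(1/m) Σ_i β·f(x_i) + log Σ_b e^{β·f(b)} − log N + Σ_j λ_j |β_j|

with per-feature penalties `λ_j = RM · β_class(m) · s_j / √m` following the
published per-class sample-size tables, scaled by a global regularization
multiplier RM. The logistic output maps raw through the entropy H of the
fitted density, `e^H·raw / (1 + e^H·raw)`, so a typical cell scores 0.5.

Candidates are ranked and filtered in the protocol's order:

1. **Significance** — partial-ROC bootstrap AUC ratios; candidates with
   P > 0.1 are removed.
2. **Omission** — fraction of independent evaluation points below the 5 %
   calibration-suitability threshold; rates > 0.1 are removed.
3. **AICc** — survivors within 2 units of the minimum are selected
   (parameters = nonzero coefficients).

The selected configuration is refit on 10 bootstrap resamples; the
per-cell median is the headline suitability and the max−min range its
uncertainty. Transfer to a target region clamps variables to their
calibration bounds; the MOP analysis flags *strict extrapolation* wherever
a target cell leaves the calibration range of any variable, and multi-GCM
futures are summarized with the nine-code gain/loss/no-change agreement
legend.

A `synthetic` module generates virtual-species inputs — spatially
autocorrelated, cross-correlated climate-like layers, occurrences sampled
from a known suitability surface with coordinate jitter and reported
uncertainties, and perturbed future stacks for pseudo-GCMs under two
emission intensities — so the whole pipeline can be validated end-to-end
with no external downloads.

## Worked example

```python
from maxenm import (
    CalibrationGrid, build_M, filter_by_uncertainty, run_calibration,
    spatial_thin, split_calibration_evaluation,
)
from maxenm.selection import best_candidate, jackknife_sets_for_grid, jackknife_variable_sets
from maxenm.synthetic import default_virtual_species

stack, vs, truth, occ = default_virtual_species(seed=42, grid_rows=50, grid_cols=50, n_presences=200)
occ = spatial_thin(filter_by_uncertainty(occ), min_distance_km=20, seed=0)
cal, ev = split_calibration_evaluation(occ, seed=1)
area = build_M(occ, stack, buffer_degrees=3)
report = jackknife_variable_sets(cal, stack, area, max_steps=4, seed=2)
sets = jackknife_sets_for_grid(report)
print("variable sets:", sets)

grid = CalibrationGrid(variable_sets=sets, rm_values=[0.5, 1.0, 2.0, 5.0],
                       feature_combos=(("L", "Q"), ("L", "Q", "P")))
results = run_calibration(grid, cal, ev, stack, seed=3, area=area,
                          max_background=1500, proc_iterations=200)
best = best_candidate(results)
print(f"{len(results)} candidates, {sum(r.selected for r in results)} selected")
print(f"best: {best.candidate_id}  p={best.proc_p:.3f}  "
      f"omission={best.omission_rate:.3f}  dAICc={best.delta_aicc:.2f}  k={best.k}")
```

prints

```
variable sets: {'set_1': ['BIO_1', 'BIO_2', 'BIO_3', 'BIO_4', 'BIO_7', 'BIO_8'], 'set_2': ['BIO_1', 'BIO_2', 'BIO_3', 'BIO_4', 'BIO_7'], 'set_3': ['BIO_1', 'BIO_2', 'BIO_3', 'BIO_4']}
24 candidates, 2 selected
best: set_3|lqp|rm=5  p=0.000  omission=0.070  dAICc=12.08  k=3
```

The jackknife pruned the four pure-noise layers (BIO_5–BIO_8, two of them
surviving an extra step) while retaining the two informative layers and
their correlated proxies. The winning candidate is significant (every
bootstrap AUC ratio beat the random expectation, p = 0), omits 7 % of the
held-out presences at the 5 % threshold, and uses 3 nonzero coefficients.
`dAICc` in the table is measured against the global minimum over all 24
candidates; selection itself compares AICc among the significant,
low-omission survivors.

The same workflow runs from the shell:

```sh
maxenm all --seed 42 --out runs/demo        # full pipeline, all artifacts
maxenm simulate --seed 42 --out fixtures/   # just the virtual species
maxenm rm-grid                              # the 19 RM values
```

`runs/demo` then contains the candidate table (CSV), the replicate models
(JSON), suitability/uncertainty/MOP/agreement rasters (ASCII grid), and a
run log with the seeds and config hash.

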