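# maxampo

Presence-only species distribution modelling for reintroduction assessment:
a randomly-clamped MaxEnt ensemble, Cohen's-kappa-thresholded **Areas of
Maximum Probability of Occupancy (AMPO)**, occupancy-overlap statistics
against observed records, and habitat-area change under SSP × GCM climate
scenarios. The package is aimed at conservation biogeographers who need the
full modelling chain — predictor preparation, model fitting, ensemble
selection, occupancy delineation, future projection — as tested, seedable
library code rather than a GUI workflow, and it ships a synthetic-island
generator with known ground truth so the whole chain can be validated
without any external data.

## The model

MaxEnt estimates a Gibbs distribution over background locations

```
q_λ(x) = exp(λ · f(x)) / Z_λ ,   Z_λ = Σ_background exp(λ · f(x))
```

where `f(x)` are feature expansions (linear, quadratic, product, hinge,
threshold) of the environmental predictors, scaled into [0, 1] with
training-background normalisers. The weights maximise the L1-penalised
presence log-likelihood

```
(1/m) Σ_i λ·f(x_i) − log Z_λ − Σ_j β_j |λ_j| ,   β_j = c_kind · s_j / √m
```

via monotone accelerated proximal gradient descent (soft-thresholding for
the L1 term). The map-scale output is the complementary log-log transform
`p = 1 − exp(−e^H · q)` with `H` the entropy of the fitted distribution.

Around that core:

* **Random clamping** — each ensemble run draws per-variable projection
  bounds from seeded quantile windows of the training distribution and a
  seeded background subsample, generating a diversity of responses.
* **Evaluation** — rank-based (Mann–Whitney) AUC, the Cohen's-kappa
  vs. threshold curve, Type I/II errors and the proportion of positive
  predictions on a held-out 20% split; the `k` best of `n` runs by test AUC
  are kept and their cloglog surfaces averaged.
* **AMPO** — each selected model is binarised at its own kappa-maximising
  threshold t*; the per-model areas are OR-combined into the global AMPO
  (planar km², rook-connectivity polygons).
* **Scenarios** — each selected model, with frozen normalisers, clamp
  bounds and t*, is re-projected onto 3 SSP × 5 GCM future climates with
  land cover and topography held constant; AMPO change is summarised per
  SSP and per GCM.
* **Diagnostics** — Mantel correlogram (permutation p-values) for spatial
  autocorrelation of the occurrences, pairwise-correlation + VIF predictor
  screening, occurrence filtering with a full removal audit.

## Worked example

```python
from maxampo import PipelineConfig, run_pipeline, summary_dict

cfg = PipelineConfig(n_models=20, k_best=5, master_seed=1)
result = run_pipeline(cfg)
print(summary_dict(result))
```

This simulates the default 120×120-cell island (100 m cells, four
elevation-driven bioclim-like layers, elevation-banded land cover, 500
presences drawn from a known logistic suitability), fits 20 randomly-clamped
MaxEnt models on a 506/127-style 80/20 presence split against a 2000-point
background, selects the 5 best by test AUC, and prints:

```
mean_selected_auc     0.780
present_ampo_km2      14.19
truth_spearman        0.959
n_scenarios           15
pct_records_in_ampo   64.1
mean_pct_change_per_ssp  {'ssp126': -80.5, 'ssp370': -95.3, 'ssp585': -98.6}
```

Reading: the five selected models discriminate presences from background
with mean test AUC 0.78; their union occupancy area is 14.19 km²; the
ensemble mean surface rank-correlates at ρ = 0.96 with the generating
suitability (the ground truth is known here, which is the point of the
synthetic island); 64% of the records fall inside the AMPO; and the
occupancy area shrinks severely under the harsher emissions pathways —
with the high-sensitivity circulation model (IPSL) losing essentially all
habitat and the low-sensitivity one (GFDL) the least, mirroring the spread
a multi-GCM ensemble is designed to expose.

The same run from a shell:

```bash
maxampo simulate --out sim/            # write the synthetic dataset
maxampo run --out results/ --seed 1    # full pipeline + report
```

`results/` contains the mean suitability and AMPO rasters, per-run metrics,
scenario and area-change tables, AMPO polygons (WKT), `report.md`, and a
`manifest.json` whose digest is identical when the run is repeated with the
same config and seed.

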