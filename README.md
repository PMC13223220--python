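# rseikit

Ecological-quality analysis of linear corridors from multiband rasters.

`rseikit` implements, as a tested and reusable pipeline:

- **Spectral indices** — the four RSEI components (NDVI, tasseled-cap
  wetness, LST decoded from digital numbers, and the SI/IBI-based
  dryness index NDBSI), growing-season compositing, and min-max
  normalization.
- **RSEI compositing** — per-year covariance PCA of the four normalized
  indices, loading-sign orientation (greenness positive), linear
  rescaling to [0, 1], and five-level quality classification.
- **Corridor statistics** — 5-km buffer / 500-m distance-belt zonal
  statistics and north-south section comparison (long-term means,
  interannual CV, Welch test, class area fractions).
- **Distribution & trends** — Gaussian KDE (Silverman default
  bandwidth), Theil-Sen slopes, Mann-Kendall with tie/continuity
  corrections, the Pettitt change-point test, OLS trends, per-pixel
  trend maps with improving/stable/degrading fractions, sub-period and
  year-over-year analyses.
- **Driver attribution** — gradient-boosted regression of RSEI on
  nine driver rasters with 1-km spatial-block train/test splitting,
  block-grouped CV and early stopping, a leakage audit (nearest
  train-test distances, approximate Moran's I, random-split inflation),
  exact tree-Shapley interpretation, feature ablation, and an OLS
  baseline.
- **Synthetic landscapes** — a seedable generator that plants a known
  north-south quality gap, section-specific driver regimes
  (natural-factor-dominated vs human-activity-dominated), spatial
  autocorrelation, and per-decade trends, so every stage is testable
  end to end without external data.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, closed forms, planted-truth recovery, leakage and
change-point properties); the remaining files are per-module unit and
property tests.

## Command line

```bash
# generate a synthetic corridor dataset (rasters + truth manifest)
rseikit simulate --out scratch/sim --seed 7

# full pipeline: simulate -> indices -> RSEI -> belts/sections ->
# KDE/trends -> attribution; prints a summary report
rseikit run-all --out scratch/run --seed 7

# attribution on an existing sample table
rseikit attribute --samples samples.csv --section south --grid reduced --seed 77

# pretty-print a saved report bundle
rseikit report --bundle scratch/run/report.json
```

Configuration is a single YAML document (see
`rseikit.pipeline.PipelineConfig.from_yaml`); all randomness flows from
named seeds and reruns are manifest-hash identical.

## Library example

```python
from rseikit.synthetic import SyntheticConfig, simulate
from rseikit.indices import compute_indices, normalize_indices
from rseikit.composite import compose_rsei
from rseikit.attribution import build_samples, spatial_block_split, fit_and_evaluate, shap_analysis

corridor, drivers, scenes, truth = simulate(SyntheticConfig(seed=7))
mask = corridor.buffer_mask
results = [compose_rsei(normalize_indices(compute_indices(s), mask), mask) for s in scenes]

samples = build_samples({r.year: r.rsei_layer for r in results}, drivers, corridor)
south = samples[samples.section == "south"].reset_index(drop=True)
model, report = fit_and_evaluate(south, grid="reduced", seed=77)
print(shap_analysis(model, south).global_ranking)
```
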