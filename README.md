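# riversdm

Riverscape species distribution modelling, end to end: synthetic stream
networks from a DEM, statistical climate downscaling, bioclimatic predictor
derivation, from-scratch maximum-entropy habitat models with candidate-model
selection, and present-vs-future habitat change accounting.

The pipeline mirrors a stream-network SDM workflow:

1. **synthetic** — drainable terrain, coarse + fine monthly climate with
   point "station" samples, parametric future-climate deltas, and presence
   records sampled from a known suitability function (so every downstream
   stage is testable against ground truth).
2. **streams** — priority-flood sink filling, D8 flow routing and
   accumulation, drainage-line extraction above 0.1 km², segmentation into
   ~100 m reaches, and per-reach geophysical attributes (drainage area,
   gradient, sinuosity, aspect, Strahler order, valley confinement, network
   distances).
3. **downscale** — geographically weighted regression of coarse climate on
   elevation, ordinary kriging of the local coefficient surfaces under an
   automatically fitted variogram, and kriged-residual station correction.
4. **bioclim** — the 19 standard bioclimatic variables plus 8 "hydroclimatic"
   variants of the precipitation variables computed from catchment-averaged
   precipitation, assembled into one per-reach predictor table.
5. **maxent** — L1-regularized Gibbs (maximum-entropy) presence-background
   model: linear/quadratic/product/hinge/threshold features, exact-L1 convex
   fitting, raw/logistic/cloglog output transforms, MaxEnt-style AICc.
6. **evaluation** — candidate grids over regularization multipliers ×
   feature-class sets, partial-ROC AUC ratios, omission rates, the selection
   cascade (pROC significance → omission ≤ E → minimum AICc), and replicate
   70/30 hold-out validation.
7. **habitat** — three-class habitat maps from the minimum-training-presence
   threshold, stream-length tallies, stable/new/lost change accounting, and
   kernel-density summaries of suitability and of suitable-reach elevation.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
for the bioclim derivation, flow-routing brute-force checks, MaxEnt KKT and
convex-oracle agreement, pROC null calibration, downscaling recovery, the
end-to-end directional climate-change result, and the selection-cascade
recovery study).

## CLI

```sh
riversdm run-all --outdir out/demo --seed 1          # full pipeline
riversdm synth --outdir out/world --seed 1           # DEM + climate + stations
riversdm network --dem out/world/dem.asc --outdir out/net
riversdm bioclim --climate out/world/climate_fine_true.csv \
    --dem out/world/dem.asc --out out/predictors.csv
```

`run-all` accepts `--config config.yaml` (see `riversdm.pipeline.
PipelineConfig` for the schema and defaults), writes every stage artifact
(ASCII-grid rasters, GeoJSON network, CSV tables, model lambdas) plus a
machine-readable `report.json` with a provenance block, and is deterministic
given `--seed`.

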