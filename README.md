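# phytosdm

Ensemble species-distribution modelling of soil phytolith abundance.
The package reconstructs long-term grass-cover proxies from soil phytolith
content (% dry soil mass) by fitting three learners — a random forest
(2000 trees, mtry = 2), a CV-tuned lasso, and an additive model of
penalized splines with null-space shrinkage — on the natural-log response,
combining them with weights proportional to their 5-fold cross-validated
prediction correlations, and projecting the ensemble across a covariate
raster stack. It also provides environmental-novelty masking (PCA distance
from sampled covariate space), Moran's I permutation diagnostics on model
residuals, NPP detrending, variable clustering at correlation distance
1 − |r|, a depth-weighted soil-covariate integrator, a Pearson correlation
screen (with a restricted coastal-range variant), and a closed-form
phytolith accumulation-time model.

A synthetic-landscape simulator generates covariate stacks with the
structure the analysis assumes (a deterministic coast-distance gradient,
correlated temperature/precipitation blocks, a soil-texture simplex, NPP)
plus a log-scale site response, so the whole pipeline is testable without
any external data downloads.

## File formats

Site tables are CSV (`site_id, x, y, <covariates...>, phytolith_pct`).
Raster stacks are one plain-text ESRI ASCII grid (`.asc`) per layer plus a
`stack.json` sidecar naming the layers; single maps are `.asc` plus a JSON
metadata sidecar. Grids are north-up, row-major, cell-center registered.

## CLI

```sh
phytosdm simulate --config landscape.yaml --out sim --seed 1
phytosdm screen --sites sim/sites.csv --out screen.csv \
    --restrict-covariate coast_distance --restrict-max 75000
phytosdm fit --learner rf --sites sim/sites.csv --seed 1 --out rf.joblib
phytosdm crossval --sites sim/sites.csv --k 5 --seed 1 --out cv.json
phytosdm ensemble-predict --fits fits/ --weights-from cv.json \
    --stack sim/stack --out pred.asc --percent
phytosdm novelty --stack sim/stack --sites sim/sites.csv \
    --npc 3 --knear 3 --nref 3000 --threshold 3 --out novelty.asc
phytosdm diagnose --residuals resid.csv --knn 5 --nsim 999 --seed 1
phytosdm accumulate --cover 0.75 --biomass 200 --production 0.04 \
    --bd 1.5 --depth 60 --threshold 0.003
phytosdm run --config pipeline.yaml --out results/
phytosdm validate-config pipeline.yaml
```

`phytosdm run` executes the full pipeline (simulating a landscape when no
site/stack paths are configured) and writes a `manifest.json` listing every
artifact with a content hash; reruns with the same config and seeds produce
identical hashes.

## Library use

```python
from phytosdm.synthetic import LandscapeConfig, simulate_dataset
from phytosdm import ensemble, diagnostics

config = LandscapeConfig(seed=1)
stack, sites = simulate_dataset(config, n_sites=120)
specs = ensemble.default_learner_specs()
model = ensemble.fit_ensemble(sites, specs, k=5, seed=1)
pred = ensemble.ensemble_predict(model, stack, back_transform_flag=True)
novelty = diagnostics.env_pc_distance(stack, sites, seed=1)
masked = diagnostics.apply_novelty_mask(pred, novelty, threshold=3.0)
```
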