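# foragekit

Quantitative detection and modelling of accept–reject foraging decisions
from animal tracking data. The package turns midpoint trajectories plus
patch geometry into discrete patch encounters, classifies each encounter
behaviorally, and fits a soft-label logistic model of the decision to
exploit a patch — with everything exercisable end-to-end on synthetic
foraging worlds with known ground truth (no external data needed).

## Modules

| module | what it does |
| --- | --- |
| `foragekit.synthetic_world` | Circular arenas with circular food patches (19-patch isometric grid or single patch), correlated-random-walk foragers with density-dependent sensing and a logistic exploit rule, and covariate-level soft-label datasets with known coefficients. |
| `foragekit.density_calibration` | Converts seeding conditions (OD600, volume, growth time) into a dimensionless relative density via edge peak-amplitude regression on radial fluorescence profiles; the reference condition (0.5 µl, OD600 = 10, 1 hr) is anchored to relative density 10. |
| `foragekit.encounter_detection` | Distance-threshold encounter detection (entry margin 0.46024 mm, near-miss filter 0.28758 mm, false-exit merge at distance-SD 0.22221 mm) and per-encounter velocity features (minimum velocity, deceleration slope, maximum velocity change; log duration, log mean on-patch velocity). |
| `foragekit.encounter_classification` | Exploit posterior p(y=1\|z) from a regularized two-component Gaussian mixture (preceded by a smoothed-bootstrap critical-bandwidth bimodality test on the PC1 projection); sensing posterior p(v=1\|w) from replicate-averaged semi-supervised soft-weighted QDA seeded by density-0 negatives and Bernoulli-drawn exploit positives; censored encounters marginalized over the unobservable features by adaptive quadrature. |
| `foragekit.exploitation_glm` | Soft-label logistic fitting (equivalently KL-divergence minimization), sequential covariate construction (ρ_k, τ_s, ρ_h, ρ_e, optional τ_t), probabilistic encounter sampling with covariate rebuild, hierarchical worm bootstrap, BIC model selection, shuffle nulls and bootstrap coefficient tests, ridge fits with cross-validated λ, strain comparisons (Z test with BH correction), first-exploitation simulations, and prediction surfaces. |
| `foragekit.pipeline_cli` | Stage orchestration (simulate → calibrate → detect → classify → fit → report), flat-file configuration, reproducibility manifests, named fixtures, and the `foragekit` console command. |

## CLI

```bash
# full synthetic pipeline into ./run_output
foragekit run --seed 1 --outdir run_output

# individual stages / named fixtures
foragekit run --seed 1 --stages simulate,detect --outdir run_output
foragekit fixture tiny-world --seed 7 --outdir fixtures
foragekit fixture glm-bench --seed 7 --outdir fixtures

# from a flat key=value config file
foragekit run --config my_run.cfg
```

All artifacts are delimited text with documented headers
(`trajectories.csv`, `arena.csv`, `encounters.csv`, `classified.csv`,
`coefficients.csv`, `ensemble.csv`) plus a JSON `manifest.json` whose
config hash makes reruns bit-identical.

## Library quick start

```python
import foragekit as fk

arena = fk.synthetic_world.generate_world("isometric_grid", 10.0, seed=1)
params = fk.synthetic_world.BehaviorParams()
trajs, truth = fk.synthetic_world.simulate_population(arena, params,
                                                      n_worms=5,
                                                      duration_s=1800, seed=1)
recs = fk.encounter_detection.detect_encounters(trajs[0], arena)

data, _ = fk.synthetic_world.generate_covariate_dataset(
    (-2.0, 1.0, 0.5, -0.5, -0.5), 200, 20, (1.0, 5.0, 10.0), seed=1)
fit = fk.exploitation_glm.fit_soft_logistic(data)
ens = fk.exploitation_glm.bootstrap_ensemble(
    data, acclimation_density=10.0, n_encounter_sets=10, n_worm_sets=50,
    seed=2, rebuild=False)
print(ens.summary())
```
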