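# prillopt

Formulation modelling and multi-response optimization for coaxial
(core–shell) prilling processes, driven entirely by small designed
experiments.

A prilling batch is described by six process variables — nozzle
configuration (a 3-level factor) plus five continuous settings (polymer
concentrations, flask pressures, airflow) — and five measured responses
(prilling capability score, mean Feret diameter, circularity, centred core
score, coating thickness). The package provides:

- **`dataset_io`** — typed dataset model, CSV/JSON I/O with `*`
  failed-batch markers, design balance reporting, and the packaged
  24-formulation reference tables.
- **`model_quality`** — percent-scale R², the regression F statistic
  derived from R² and caller-supplied degrees of freedom, critical F by
  quantile inversion, and the significance verdict.
- **`neurofuzzy`** — interpretable additive fuzzy-spline models (triangular
  partitions, tensor-product submodels of ≤ 2 inputs, ridge least squares),
  greedy structure search scored by a structural-risk criterion, and
  IF–THEN rule extraction.
- **`ann_surrogate`** — per-response 6-2-1 feed-forward networks with
  asymmetric sigmoid hidden units, trained full-batch by RPROP with
  optional early stopping, plus 80/20 splitting and seed scanning.
- **`desirability_ga`** — UP/TENT desirability functions, weighted
  aggregation, and an elitist genetic algorithm over the design space.
- **`particle_metrics`** — Probit (log-normal) size-distribution fitting,
  geometric mean/GSD, drug loading and encapsulation-efficiency
  calculators including the indirect mass-balance estimate.
- **`synthetic_rig`** — a virtual prilling rig (known smooth ground truth,
  Gaussian noise, a nozzle-blockage failure region) and a log-normal
  particle-population sampler, used for parameter-recovery and end-to-end
  tests.
- **`cli`** — `prillopt validate | model | optimize | particles | simulate`.

## CLI quick tour

```bash
# validate a formulation table (the packaged schema; '*' marks failed batches)
prillopt validate my_design.csv

# fit neuro-fuzzy + surrogate models for every response
prillopt model my_design.csv --seed 10000 --out models/

# GA optimization of overall desirability over saved surrogates
prillopt optimize models/ann_*.json --desirability desirability.csv \
    --seed 1 --out report.json --trace-out trace.csv

# particle size-distribution report from an image-analysis export
prillopt particles particles.csv

# generate a synthetic dataset from the virtual rig
prillopt simulate --n 24 --seed 0 --out synthetic.csv
```

Exit codes: 0 success, 2 usage/format error, 1 runtime failure.

## Notes on conventions

- R² is reported on the percent scale; the regression F is
  `(R²/v1)/((1−R²)/v2)`. Degrees of freedom are always caller-supplied.
- UP desirability ramps from `min` to 1 at `mid1` and stays 1 through
  `max` (the ramp-to-mid2 alternative is selectable); TENT ramps up to a
  plateau on `[mid1, mid2]` and back to 0 at `max`. Aggregation is the
  weighted arithmetic mean (geometric mode available).
- Failed batches are kept in datasets; each modelling stage chooses its
  inclusion rule. `dataset_io.score_failed_blockage` optionally scores
  failed-blockage batches 0 on the prilling-capability scale.
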