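# phenoswitch

Quantitative analysis of bistable phenotype heterogeneity in isogenic
multicellular yeast populations.

Settling-selected multicellular *Saccharomyces cerevisiae* genotypes carrying a
loss-of-function ACE2 allele maintain two coexisting morphotypes within a
single clonal population: large multicellular "snowflake" clusters and small
ancestral-like clusters of one to a few cells (3–13 μm diameter).  This
package is for researchers who want to quantify that bistability from
particle-counter style diameter data and to test whether the phenotype-count
dynamics over a growth cycle are consistent with stochastic phenotypic
switching.

It provides:

* **Size-distribution statistics** (`phenoswitch.sizedist`) — two-component
  univariate Gaussian mixture decomposition by EM, a ΔBIC bimodality decision,
  the kernel-density overlap index η (integral of the pointwise minimum of two
  KDEs), Ward-D2 hierarchical clustering of overlap matrices, and hard
  threshold classification into small (≤ 13 μm) and large (> 13 μm) size
  classes.
* **A two-phenotype switching model** (`phenoswitch.model`) — coupled ODEs for
  large-cluster abundance *M* and small-cluster abundance *U*,

  ```
  dM/dt = α · log₂(M) + η(t) + γ·U
  dU/dt = S(t) · β · M − γ·U,      S(t) = 1 / (1 + exp(−k (t − t_switch)))
  ```

  integrated with explicit Euler steps (Euler–Maruyama for the additive noise
  term η(t)), plus a deterministic grid search that fits (α, β, γ, k) to
  observed small-cluster fractions at the assay times 12, 20, 24 and 48 h by
  minimising the RMSE prediction error, reporting R² and residual diagnostics.
* **A synthetic-data generator** (`phenoswitch.synthetic`) — truncated
  bimodal diameter samples emulating Coulter-counter exports and
  phenotype-count time courses with binomial counting noise, so the entire
  analysis is testable without instrument data.
* **A reproducible pipeline and CLI** (`phenoswitch.pipeline`,
  `phenoswitch` command) — YAML-configured end-to-end runs with a manifest
  (seed, versions, per-stage timing, content hash per output) and a plain-text
  summary.

## Worked example

Run the self-contained pipeline (synthetic data only):

```bash
phenoswitch run --config cfg.yaml
```

with `cfg.yaml`:

```yaml
seed: 1
output_dir: demo_out
particles:
  synthetic: {n_samples: 3, n_per_sample: 2000}
observations:
  synthetic: {}
```

produces `demo_out/summary.txt`:

```
phenoswitch pipeline summary
seed: 1

samples: 3; observation timepoints: 4
  S1@24h: bimodal; means (6.061, 25.075) um; weight_small 0.495
  S2@24h: bimodal; means (6.149, 25.141) um; weight_small 0.493
  S3@24h: bimodal; means (6.033, 24.877) um; weight_small 0.497
overlap eta range: 0.9785 - 0.9861 over 3 samples
  S1@24h: fraction_small 0.4980 at 13 um
  S2@24h: fraction_small 0.4960 at 13 um
  S3@24h: fraction_small 0.5020 at 13 um
best fit: alpha=1 beta=0.005 gamma=0 k=0.001; RMSE=0.00272142; R2=0.9669
```

Reading this: each synthetic sample is decomposed into a small mode near 6 μm
and a large mode near 25 μm with roughly equal weights and is declared bimodal
by ΔBIC; the three replicate distributions overlap almost completely
(η ≈ 0.98); about half of the particles fall in the small size class at the
13 μm cutoff; and the grid search recovers the switching-model tuple
(α = 1, β = 0.005, γ = 0, k = 0.001) that generated the count time course,
with an RMSE of 0.0027 in fraction units against the binomially noised counts
and R² = 0.97 between predicted and observed fractions.

The same stages are available individually (`phenoswitch simulate`,
`phenoswitch fit`, `phenoswitch mixture`, `phenoswitch overlap`,
`phenoswitch classify`, `phenoswitch synth`) and as plain library calls:

```python
from phenoswitch import SwitchingParams, simulate, predicted_fractions

traj = simulate(SwitchingParams(alpha=1.0, beta=0.005, gamma=0.0, k=0.001))
print(predicted_fractions(traj, [12, 20, 24, 48]))
# [0.0127181  0.02084731 0.024972   0.04980111]
```

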