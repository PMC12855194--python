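# Methods

## The switching model

The model describes a batch growth cycle of an isogenic multicellular yeast
population as two coupled pools: large multicellular clusters *M* and small
ancestral-like clusters *U*.

```
dM/dt = α · log₂(M) + η(t) + γ·U
dU/dt = S(t) · β · M − γ·U
```

Large-cluster growth is expressed through the doubling time as α·log₂(M)
(α in 1/h); M = 1 is a fixed point of that law, so trajectories require
m0 > 1 and M is clamped at 1 + 1e−9 after every step (the clamp is asserted
in tests never to activate for default parameter ranges).  Small clusters are
produced from large clusters at rate β (1/h), gated by a logistic switch
S(t) = 1/(1 + exp(−k(t − t_switch))) with steepness k (1/h).  The midpoint
default t_switch = 20 h places the switch at the post-diauxic transition of a
typical batch culture, where small-cluster production is first observed; the
logistic form itself is a modelling choice — only "a sigmoid with steepness
k" is constrained by the biology.  γ (1/h) is the reversion rate of small
clusters back to the multicellular pool; the empirically supported regime has
γ = 0, in which case U is non-decreasing.  η(t) is an additive fluctuation in
M growth, integrated Euler–Maruyama style: each Euler step adds
σ_η·√dt·N(0,1) to M.  σ_η = 0 (the default, and the mode used for all
fitting) gives a fully deterministic model that ignores the seed.

Time is in hours throughout.  Default initial conditions are m0 = 2 (one
doubling above the fixed point) and u0 = 0.

### Integration

Explicit Euler at dt = 0.01 h. The scheme is the simplest one consistent with
the additive noise term; in deterministic mode it is verified against a
high-order integrator (DOP853 at rtol = 1e−12) to within 0.5% over 48 h, and
halving dt moves the predicted fractions at the 12/20/24/48 h observation
times by less than 1e−4.  A guard raises a step-size error whenever a single
step changes M by more than 50%; inside the grid search such tuples are
recorded with an infinite objective instead of aborting the fit.  dt is
capped at 0.1 h.

### Fitting

The fit is a deterministic grid search over (α, β, γ, k) with t_switch, m0,
u0 fixed.  The objective is the RMSE between predicted and observed
small-cluster fractions U/(U+M) at the observation times (fractions are
obtained by linear interpolation on the simulation grid).  R² of predicted
versus observed values and the residual SD are reported alongside.  Ties in
the argmin (e.g. β = 0 making k unidentifiable) are broken lexicographically
by (α, β, γ, k) ascending — deterministic and documented.

The default grid is α ∈ {0.05, 0.2, 1.0}, β ∈ {0.001, 0.005, 0.02},
γ ∈ {0, 0.05}, k ∈ {0.001, 0.1, 1.0}.  Spacings were set by a power analysis
of the deterministic model under binomial counting noise at 10,000 particles
per timepoint: a grid value is admitted only if swapping it for its neighbour
shifts the predicted fraction time course by well more than the counting-noise
RMSE (~0.0016 in fraction units at these dynamics).  The small-cluster
fraction saturates in α — increasing α inflates M and U nearly
proportionally — so α values above the truth are statistically
indistinguishable from it at this noise level; the α grid therefore spans
downward from 1.  With this grid, noise-free self-fits recover every one of
the 54 tuples exactly, and binomially-noised fits recover the generating
tuple in ≥ 90% of replicates.

## Size-distribution statistics

**Mixture decomposition.**  Two-component univariate Gaussian mixtures are
fitted by EM with deterministic initialisation: means at the 25th/75th sample
quantiles, both SDs at the sample SD, equal weights.  The log-likelihood is
non-decreasing at every iteration (an EM guarantee, asserted in tests);
convergence is |ΔLL| < tol, default tol = 1e−6 with max_iter = 2000.  The
tolerance is deliberately looser than machine precision because EM on
unimodal data drifts along a likelihood plateau for thousands of iterations;
1e−6 resolves the ΔBIC decision (which operates on differences of order 10)
with orders of magnitude to spare.  Component SDs are floored at 1e−6 μm to
prevent the likelihood singularity of a collapsing component; a collapse is
flagged (`sd_floor_hit`), not silently fixed.  Components are returned sorted
by mean (ties by SD).  A closed-form single-Gaussian fit and both BIC values
accompany every fit.  Samples with fewer than 10 points or zero variance are
rejected as degenerate.

**Bimodality decision.**  Bimodal iff BIC₁ − BIC₂ > 10 (strict), i.e. a
decisive BIC margin in the conventional interpretation; a ΔBIC exactly at the
threshold is unimodal.  Non-converged fits are refused rather than decided.
The decision rule stands in for an unnamed multimodality test in the original
workflow; it is consistent with mixture-model selection practice but is not
claimed to be the identical procedure.

**Overlap index.**  η(a, b) integrates min(f̂ₐ, f̂ᵦ) over a 1024-point
equispaced grid spanning the union of both sample ranges padded by three
bandwidths on each side.  Densities are Gaussian KDEs with the Silverman
rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) computed per sample —
the same default as the R `density()`/`overlapping` convention the field
uses.  The trapezoidal integral is clamped to [0, 1].  η is symmetric, ≥ 0.99
for a sample against itself, and within 0.03 of the closed form 2Φ(−1) for
unit-variance Gaussians two σ apart (verified on 5,000-point samples).

**Clustering.**  Overlap-matrix rows are feature vectors; agglomeration uses
Euclidean inter-row distances with Ward-D2 linkage via
`scipy.cluster.hierarchy.linkage(method="ward")`, which matches R's
`hclust(ward.D2)` on Euclidean distances.  Merge heights are non-decreasing;
a 3-item Lance–Williams enumeration serves as the test oracle.

**Size classes.**  A particle is small iff diameter ≤ threshold (default
13 μm) — the small class is closed at its upper boundary, matching the 3–13 μm
inclusive definition of the small-propagule class.  The threshold is a plain
number, so the same rule applies to image-derived area thresholds (e.g. 7000
squared pixels) on tabulated sizes.

## Synthetic data

The generator emulates what the analysis assumes about the instrument data,
not any particular instrument file format.

* **Diameters**: a two-component Gaussian mixture truncated below a detection
  threshold by rejection sampling (every kept diameter strictly exceeds the
  threshold).  Defaults — equal weights, small mode 6 ± 1.5 μm, large mode
  25 ± 5 μm, threshold 3 μm — place essentially all small-mode mass inside
  the 3–13 μm class and all large-mode mass above 13 μm.  These defaults are
  conventions consistent with the published class boundaries, not calibrated
  per-strain values (per-strain descriptive statistics live in supplementary
  material not shipped here).  Draws are bitwise-reproducible per seed and
  match the truncated target density (KS test at α = 0.01 across seeds).
* **Count time courses**: the switching model is simulated forward and the
  small-cluster fraction read off at the observation times (default 12, 20,
  24, 48 h); with binomial sampling enabled, the small count at each time is
  Binomial(N, p) with N = 10,000 by default.  Binomial noise is the natural
  counting model for particle tallies; the original workflow does not specify
  one.

What the generator does **not** emulate: instrument measurement error on
individual diameters, non-Gaussian or skewed modes, inter-replicate biological
variability beyond sampling noise, coincidence/aperture artefacts, or any
correlation between a sample's diameters.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to real-instrument pathology.

## Pipeline

A single YAML config drives synth → mixture → overlap/clustering →
classification → model fit.  Per-stage seeds derive from the master seed by a
fixed counter scheme (stage s, item i → master + 100·s + i), so stochastic
stages are reproducible in isolation.  Results depend only on config and
seed; the manifest records the config echo, seed, package versions, per-stage
wall time and a SHA-256 per output file.  Particle CSVs are written with
`%.17g` floats and read with round-trip float parsing so that a write → read
cycle is bitwise exact.

## Known limitations

* The grid search is a grid search: no continuous refinement between grid
  values, by design.
* α is only weakly identified by fraction data (see above); conclusions about
  α from count time courses alone are limited to its lower range.
* The overlap index is computed on raw diameters; binned-count variants would
  differ slightly.
* The ΔBIC bimodality rule is a stated substitute for an unspecified
  multimodality test, and RMSE is a stated substitute for an unavailable
  "prediction error" definition; R² is reported alongside for comparability.
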