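# Methods

## The simulation model

`splatsim` simulates a genes × cells matrix of non-negative integer counts
Y<sub>ij</sub> from a hierarchical gamma-Poisson model with multiplicative
structure:

1. **Gene base means.** μ<sub>i</sub> ~ Gamma(α, rate β), i = 1…N.
2. **Expression outliers.** With probability π<sup>O</sup> a gene is a
   high-expression outlier: its mean is replaced by median(μ) ·
   LogNormal(μ<sup>O</sup>, σ<sup>O</sup>).  Non-outlier genes keep their
   mean and a recorded factor of exactly 1.
3. **Structure.** Per-group differential-expression (DE) factors, per-batch
   factors, or differentiation-path trajectories multiply the base means per
   cell (details below).
4. **Library sizes.** L<sub>j</sub> ~ LogNormal(μ<sup>L</sup>, σ<sup>L</sup>).
   Each cell's mean vector is rescaled so that its sum is exactly
   L<sub>j</sub>; sequencing depth is therefore controlled independently of
   relative expression, and Σ<sub>i</sub> cell_means<sub>ij</sub> =
   L<sub>j</sub> holds to machine precision (tested at 1e-6 relative).
5. **Mean–variance trend.** One χ²<sub>df</sub> variate q<sub>i</sub> is
   drawn per gene and the biological coefficient of variation is
   BCV<sub>ij</sub> = (φ + 1/√mean<sub>ij</sub>) · √(df/q<sub>i</sub>) — the
   standard common-dispersion + Poisson-noise decomposition, decreasing in
   the mean.  Trended means λ<sub>ij</sub> ~ Gamma(shape = 1/BCV²,
   rate = 1/(BCV²·mean)) have expectation equal to the cell mean and CV
   equal to the BCV.
6. **Counts.** Y<sub>ij</sub> ~ Poisson(λ<sub>ij</sub>).  Marginally (for
   df → ∞) this is negative binomial with dispersion BCV².
7. **Dropout (optional).** With x = ln λ<sub>ij</sub>, a count is zeroed by
   a Bernoulli draw with probability 1/(1 + e<sup>k(x − x₀)</sup>): exactly
   50% at x = x₀, decreasing with expression for k > 0.  The pre-dropout
   matrix and the mask are both returned.

All intermediate layers (base means, outlier flags/factors, DE and batch
factors, library sizes, cell means, BCV, trended means, dropout
probabilities and mask) are returned in the `SimulationResult`, so simulated
datasets carry their full ground truth.

### Groups, batches, paths

*Groups.*  Cells draw a group label from `group_probs`; each gene × group
cell gets a DE factor that is LogNormal(de_loc, de_scale) with probability
`de_prob` (inverted to its reciprocal with probability `de_down_prob`) and
exactly 1 otherwise.

*Batches.*  Cells are split into contiguous blocks of sizes `batch_cells`;
batch factors are LogNormal(batch_fac_loc, batch_fac_scale) applied to **all**
genes of a batch's cells.  With a single batch the factor matrix is all ones,
so the default single-population simulation stays a pure gamma-Poisson
hierarchy.

*Paths.*  A path's endpoint expression state is defined by DE factors as
above; a path with `path_from = t` starts from the factor vector at the end
of path t (0 = the all-ones root), supporting branching topologies.  Factor
trajectories interpolate log-factors linearly across `path_n_steps` steps;
with probability `path_nonlinear_prob` a gene instead follows the
exponential of a Brownian bridge (per-step sd `path_sigma_fac`), thinned to
~10 evenly spaced knots and smoothed with an Akima spline — both endpoints
are met exactly.  Cells land on a step through a position fraction drawn
from Beta(2s, 2(1−s)) for skew s: uniform at s = 0.5, concentrated at the
path end as s → 1.  The Beta family and the ~10-knot density are this
package's choices where only the concepts (skew, bridge + Akima smoothing)
are fixed.

### Randomness

One seed drives the whole simulation.  Substreams are spawned in a fixed,
append-only order (base means, outliers, DE, batch, path, group assignment,
library sizes, BCV, trend, Poisson, dropout), so gene-level draws are
unchanged when the number of cells changes, and identical (params, mode)
pairs are bit-identical.  A consequence used by the tests: groups mode with
`group_probs=[1.0]` and `de_prob=0` reproduces single mode exactly.

### Baselines

*simple*: gamma gene means, i.i.d. NB counts per cell with one fixed
dispersion (default 0.1).  *lun*: adds a per-cell factor c<sub>j</sub> ~
Normal(1, var 0.5); the cell's means are scaled by 2^c<sub>j</sub>; optional
groups receive a fixed fold change (default 5) on a `de_prob` fraction of
genes, up-regulated in the assigned group.  Gamma defaults (shape 2, rate 2
for lun; 0.6, 0.3 for simple), the lun dispersion and the fold change are
implementation defaults — the sources describe the model forms, not these
values.

## Parameter estimation

Estimation uses only the count matrix.  Library-size normalization rescales
every cell to the median cell total and drops all-zero genes.  Conventions:
type-7 (linear-interpolation) quantiles, MAD with the 1.4826 consistency
constant, log-normal fits by closed-form MLE (mean and ddof = 0 sd of logs).

- **α, β** — gamma fit to the 10%-winsorized normalized gene means.  The fit
  minimizes the Cramér–von Mises distance (moment-initialized Nelder–Mead)
  rather than maximizing likelihood: winsorizing places point masses at the
  clamp values, and gamma MLE on such data overestimates the shape by ~35%
  in our pilots, while the minimum-distance fit tracks the bulk and recovers
  the shape within ~10%.  Note the identifiability caveat: the simulation
  rescales every cell to its library size, so base means (and hence β) are
  identified only up to scale; β̂ is on the "normalized to median library"
  scale.
- **μ<sup>L</sup>, σ<sup>L</sup>** — log-normal MLE on the raw cell totals.
- **π<sup>O</sup>, μ<sup>O</sup>, σ<sup>O</sup>** — outliers are genes whose
  normalized mean exceeds median + 2·MAD; π<sup>O</sup> is the detected
  fraction, and a log-normal is fitted to outlier-mean/median ratios (with
  documented fallback defaults 4.0/0.5 when no or one outlier is found).
  This rule has an irreducible false-positive floor: even for a symmetric
  mean distribution ~1.7% of clean genes exceed the threshold, and for
  heavy-tailed gamma means the floor grows (≈ +0.13 at shape 0.6, +0.02 at
  shape 100).  Detected fractions are therefore upper-biased estimates of
  the simulated probability; recovery is exact only in the near-symmetric
  limit, and the false positives also dilute the fitted factor location.
- **φ (common BCV)** — a single shared NB dispersion maximizes the summed
  NB log-likelihood over normalized counts with gene means plugged in
  (bounded search on log-dispersion in [1e-6, 10]; the continuous
  gamma-function likelihood handles real-valued normalized counts).  The
  affine correction φ = 0.1 + 0.25·raw is then applied.  The correction's
  coefficients were calibrated against a different raw estimator than ours,
  so round-trip recovery of φ from simulated data is order-of-magnitude
  (observed ≈ 0.15 for a simulated 0.1); the raw profile estimator itself
  recovers a true NB dispersion within a few percent.
- **x₀, k (dropout)** — nonlinear least squares of per-gene zero proportion
  against log normalized mean under the logistic model, initialized at the
  gene nearest a 50% zero proportion and k = 1.  A matrix with no zeros
  returns the sentinel `None` (dropout not estimable — real UMI data often
  has no excess zeros).  Because the fit uses *observed* zeros and
  *observed* (post-dropout) means, it carries two opposing systematics:
  Poisson sampling zeros shift the apparent midpoint up (≈ +0.45 at
  x₀ = 0), while dropout-shrunken observed means shift it down (≈ −0.5 at
  x₀ = 2).  The two balance for midpoints around 0.25–1.25, where recovery
  is within ±0.3; the recovery tests run at x₀ = 0.75 and the biased
  regimes are asserted as directional properties.

`splat_estimate` composes the above, tags every fitted field
`provenance="estimated"`, and leaves non-estimable fields (group/batch/path
structure and the BCV degrees of freedom df) at their defaults.  For the
baselines, `simple_estimate` fits means and dispersion; `lun_estimate` only
the gamma means (the model has no estimation procedure for its other
parameters).

## Comparison engine

`summarize_dataset` computes seven statistics: per-gene mean and variance on
the log2(CPM + 1) scale (a documented choice — bounded and comparable across
depths; raw-scale variants via `log_scale=False`), per-gene and per-cell
zero fractions and raw library sizes, plus the mean–variance and mean–zeros
pairings (gene means include zero-count cells).  Differences from a
reference are taken between sorted vectors (distribution-level comparison);
for the two relationship metrics both datasets' genes are ordered by mean
expression and the companion statistic differenced.  Unequal sizes are
reconciled on a common quantile grid (the original comparisons used
equal-sized datasets; the grid is this package's extension).  The MAD —
median absolute sorted difference — is computed per metric, and simulations
are ranked per metric with ties sharing the minimum rank.

## Numerical choices and degenerate inputs

- BCV = 0 in the trend step degenerates to the cell mean itself (the gamma
  shape is clipped at 1/1e-18).
- Zero-rate Poisson cells give zero counts; log(0) in the dropout logistic
  yields probability 1 for k > 0 (the count is already zero).
- σ = 0 log-normals are exact point masses; skew 0/1 path positions pin
  cells to the path start/end.
- Validation reports *all* parameter violations as data
  (`validate_params`), not exceptions; simulators refuse invalid parameter
  objects with the full list.
- Estimators raise on degenerate inputs they cannot handle (zero-total
  cells, constant means, single cells, all-zero matrices) and name the
  offending cell/field.

## What the synthetic tests do and do not show

The test suite's "real" datasets are themselves draws from this package's
models, so recovery tests demonstrate internal consistency — each estimator
returns the parameters that generated the data, where its assumptions hold —
not fidelity to any laboratory dataset.  Features of real scRNA-seq data
that the generator does not emulate include gene–gene correlation, cell
cycle and other structured covariates, gene-length/GC effects, ambient RNA
and doublets.  Problem sizes in tests and the acceptance script (up to
17,000 genes, 5,000 × 1,000 matrices, 5 seeds per recovery setting) were
chosen so the whole suite runs in minutes while keeping Monte-Carlo error
well inside each stated tolerance.

## Known limitations

- The default parameter values are configuration, not estimates from any
  particular dataset; realistic UMI-like output needs `splat_estimate` on
  data of interest.
- φ round-trip calibration is approximate (see above); df for the BCV
  chi-squared is never estimated.
- The dropout and outlier estimators carry the documented systematic biases;
  both follow the published estimation procedures deliberately.
- The chi-squared BCV variate is shared per gene (one draw per gene, all
  cells); a per-gene-and-cell variant is a possible extension flagged for
  sensitivity testing.
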