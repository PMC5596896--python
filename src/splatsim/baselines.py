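"""Reference simulations: the simple and Lun-style negative-binomial models.

Both are deliberately minimal baselines against which the full hierarchical
simulation can be compared.  They return the same :class:`SimulationResult`
container with the unused layers (outliers, dropout, BCV trend) set to their
trivial values so that every downstream consumer works unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import LunParams, SimpleParams, validate_params
from .splat import SimulationResult

__all__ = ["nb_counts", "simple_simulate", "lun_simulate"]


def nb_counts(mean, dispersion, rng) -> np.ndarray:
    """Negative binomial draws with mean ``mean`` and dispersion ``dispersion``.

    Parameterized so that Var = mean + dispersion * mean^2; size = 1/dispersion.
    """
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    return rng.negative_binomial(r, r / (r + mean))


def _trivial_result(counts, base_means, cell_means, de_factors, cell_meta) -> SimulationResult:
    n_genes, n_cells = counts.shape
    return SimulationResult(
        counts=counts,
        counts_pre_dropout=counts,
        base_means=base_means,
        outlier_flags=np.zeros(n_genes, dtype=bool),
        outlier_factors=np.ones(n_genes),
        library_sizes=cell_means.sum(axis=0),
        de_factors=de_factors,
        batch_factors=np.ones((n_genes, 1)),
        cell_meta=cell_meta,
        cell_means=cell_means,
        bcv=np.zeros((n_genes, n_cells)),
        trended_means=cell_means,
        dropout_prob=np.zeros((n_genes, n_cells)),
        dropout_mask=np.ones((n_genes, n_cells), dtype=bool),
    )


def simple_simulate(p: SimpleParams) -> SimulationResult:
    """Gamma gene means, i.i.d. negative-binomial counts per cell.

    No library-size, outlier, or dropout layers: every cell shares the same
    expected expression profile and a single fixed dispersion.
    """
    violations = validate_params(p)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(map(str, violations)))
    ss = np.random.SeedSequence(p.seed).spawn(2)
    rng_mean, rng_counts = map(np.random.default_rng, ss)

    means = rng_mean.gamma(p.mean_shape, 1.0 / p.mean_rate, size=p.n_genes)
    mean_matrix = np.repeat(means[:, None], p.n_cells, axis=1)
    counts = nb_counts(mean_matrix, p.dispersion, rng_counts)

    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"Cell{j + 1}" for j in range(p.n_cells)],
            "group": np.ones(p.n_cells, dtype=int),
            "batch": np.ones(p.n_cells, dtype=int),
        }
    )
    return _trivial_result(counts, means, mean_matrix, np.ones((p.n_genes, 1)), cell_meta)


def lun_simulate(p: LunParams) -> SimulationResult:
    """Simple model plus a per-cell scaling factor and optional fixed-fold DE.

    Cell factors are Normal(``cell_factor_mean``, variance
    ``cell_factor_var``) draws; the inverse-log2 transformed factor
    (``2**factor``) scales every gene mean in that cell, emulating technical
    scaling differences between cells.  With ``n_groups > 1``, a
    ``de_prob`` fraction of genes per group is up-regulated by the fixed
    ``de_fold_change`` in that group.  Cells are split between groups in
    contiguous, near-equal blocks.

    The drawn (pre-transformation) cell factors are recorded in
    ``cell_meta["cell_factor"]``.
    """
    violations = validate_params(p)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(map(str, violations)))
    ss = np.random.SeedSequence(p.seed).spawn(4)
    rng_mean, rng_fac, rng_de, rng_counts = map(np.random.default_rng, ss)

    means = rng_mean.gamma(p.mean_shape, 1.0 / p.mean_rate, size=p.n_genes)
    cell_factors = rng_fac.normal(p.cell_factor_mean, np.sqrt(p.cell_factor_var), size=p.n_cells)

    de_factors = np.ones((p.n_genes, p.n_groups))
    for g in range(p.n_groups):
        chosen = rng_de.random(p.n_genes) < p.de_prob
        de_factors[chosen, g] = p.de_fold_change
    group_sizes = [len(b) for b in np.array_split(np.arange(p.n_cells), p.n_groups)]
    groups = np.repeat(np.arange(1, p.n_groups + 1), group_sizes)

    mean_matrix = means[:, None] * de_factors[:, groups - 1] * np.exp2(cell_factors)[None, :]
    counts = nb_counts(mean_matrix, p.dispersion, rng_counts)

    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"Cell{j + 1}" for j in range(p.n_cells)],
            "group": groups,
            "batch": np.ones(p.n_cells, dtype=int),
            "cell_factor": cell_factors,
        }
    )
    return _trivial_result(counts, means, mean_matrix, de_factors, cell_meta)
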