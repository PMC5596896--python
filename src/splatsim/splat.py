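"""The splat gamma-Poisson count simulation.

The pipeline simulates a genes x cells count matrix hierarchically:

1.  gene base means from a Gamma(shape, rate) distribution;
2.  expression-outlier genes replaced by median(mean) times a log-normal
    inflation factor;
3.  multiplicative structure — per-group differential-expression factors,
    per-batch factors, or differentiation-path factor trajectories — applied
    to the base means per cell;
4.  per-cell rescaling so each cell's expected total equals its simulated
    log-normal library size;
5.  a mean-variance trend enforced by drawing a biological coefficient of
    variation (BCV) per gene from a scaled inverse chi-squared distribution
    and resampling the cell means from a gamma with that CV;
6.  Poisson counts with the trended means as rates;
7.  optional logistic dropout: counts are zeroed by a Bernoulli draw whose
    probability decreases with log expression.

All intermediate layers are returned in a :class:`SimulationResult` so that
downstream evaluations have access to the full simulation truth.

Randomness is consumed from named substreams spawned in a fixed order from the
seed, so gene-level draws do not change when the number of cells changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator
from scipy.special import expit

from .params import SplatParams, validate_params

__all__ = [
    "SimulationResult",
    "simulate_base_means",
    "apply_expression_outliers",
    "simulate_library_sizes",
    "simulate_de_factors",
    "assign_cells",
    "simulate_batch_factors",
    "compute_cell_means",
    "simulate_bcv",
    "simulate_trended_means",
    "simulate_counts",
    "dropout_probability",
    "simulate_dropout",
    "brownian_bridge",
    "simulate_path_factors",
    "assign_path_positions",
    "splat_simulate",
]

MODES = ("single", "groups", "paths")

#: Fixed spawn order of RNG substreams; append-only to preserve streams.
_STREAMS = (
    "base_means",
    "outliers",
    "de",
    "batch",
    "path",
    "group",
    "libsize",
    "bcv",
    "trend",
    "poisson",
    "dropout",
)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class SimulationResult:
    """A simulated count matrix together with every intermediate truth layer.

    ``counts`` is the final output; ``counts_pre_dropout`` the counts before
    the dropout mask.  Factor matrices hold 1 where no effect applies.  The
    invariants ``counts == counts_pre_dropout * dropout_mask`` and
    ``cell_means[:, j].sum() == library_sizes[j]`` hold by construction.
    """

    counts: np.ndarray
    counts_pre_dropout: np.ndarray
    base_means: np.ndarray
    outlier_flags: np.ndarray
    outlier_factors: np.ndarray
    library_sizes: np.ndarray
    de_factors: np.ndarray
    batch_factors: np.ndarray
    cell_meta: pd.DataFrame
    cell_means: np.ndarray
    bcv: np.ndarray
    trended_means: np.ndarray
    dropout_prob: np.ndarray
    dropout_mask: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return [f"Gene{i + 1}" for i in range(self.n_genes)]

    @property
    def cell_ids(self) -> list[str]:
        return [f"Cell{j + 1}" for j in range(self.n_cells)]


# ---------------------------------------------------------------------------
# elementary steps


def simulate_base_means(n_genes, mean_shape, mean_rate, rng) -> np.ndarray:
    """Draw ``n_genes`` gene means from Gamma(``mean_shape``, rate ``mean_rate``)."""
    if not mean_shape > 0 or not mean_rate > 0:
        raise ValueError(f"gamma shape and rate must be > 0 (got {mean_shape}, {mean_rate})")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    return rng.gamma(mean_shape, 1.0 / mean_rate, size=n_genes)


def apply_expression_outliers(base_means, out_prob, out_loc, out_scale, rng):
    """Replace a Bernoulli(``out_prob``) subset of gene means with outliers.

    Flagged genes get median(base_means) times a LogNormal(out_loc, out_scale)
    inflation factor; other genes keep their mean and a factor of exactly 1.

    Returns ``(means, flags, factors)``.
    """
    base_means = np.asarray(base_means, dtype=float)
    if base_means.size == 0:
        raise ValueError("base_means must be non-empty")
    if not (0.0 <= out_prob <= 1.0):
        raise ValueError(f"out_prob must be in [0, 1], got {out_prob}")
    if out_scale < 0:
        raise ValueError(f"out_scale must be >= 0, got {out_scale}")
    flags = rng.random(base_means.size) < out_prob
    factors = np.ones(base_means.size)
    factors[flags] = rng.lognormal(out_loc, out_scale, size=int(flags.sum()))
    means = base_means.copy()
    means[flags] = np.median(base_means) * factors[flags]
    return means, flags, factors


def simulate_library_sizes(n_cells, lib_loc, lib_scale, rng) -> np.ndarray:
    """Draw per-cell library sizes from LogNormal(``lib_loc``, ``lib_scale``)."""
    if lib_scale < 0:
        raise ValueError(f"lib_scale must be >= 0, got {lib_scale}")
    return rng.lognormal(lib_loc, lib_scale, size=n_cells)


def _per_group(value, n_groups, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n_groups)
    if arr.size != n_groups:
        raise ValueError(f"{name} needs one value per group ({n_groups}), got {arr.size}")
    return arr


def simulate_de_factors(n_genes, n_groups, de_prob, de_down_prob, de_loc, de_scale, rng) -> np.ndarray:
    """Multiplicative differential-expression factors, genes x groups.

    Independently per gene and group: with probability ``de_prob`` the factor
    is LogNormal(``de_loc``, ``de_scale``), inverted to its reciprocal with
    probability ``de_down_prob``; otherwise exactly 1.  The per-group
    arguments may be scalars or length-``n_groups`` sequences.
    """
    de_prob = _per_group(de_prob, n_groups, "de_prob")
    de_down_prob = _per_group(de_down_prob, n_groups, "de_down_prob")
    de_loc = _per_group(de_loc, n_groups, "de_loc")
    de_scale = _per_group(de_scale, n_groups, "de_scale")
    for name, arr in (("de_prob", de_prob), ("de_down_prob", de_down_prob)):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} entries must be in [0, 1], got {arr}")
    if np.any(de_scale < 0):
        raise ValueError(f"de_scale entries must be >= 0, got {de_scale}")

    factors = np.ones((n_genes, n_groups))
    for g in range(n_groups):
        is_de = rng.random(n_genes) < de_prob[g]
        fac = rng.lognormal(de_loc[g], de_scale[g], size=n_genes)
        down = rng.random(n_genes) < de_down_prob[g]
        fac = np.where(down, 1.0 / fac, fac)
        factors[:, g] = np.where(is_de, fac, 1.0)
    return factors


def assign_cells(n_cells, group_probs, batch_cells, rng):
    """Assign each cell a group (categorical draw) and a batch (fixed blocks).

    Returns 1-based integer label arrays ``(groups, batches)``.
    """
    group_probs = np.asarray(group_probs, dtype=float)
    if abs(group_probs.sum() - 1.0) > 1e-9 or np.any(group_probs < 0):
        raise ValueError(f"group_probs must be non-negative and sum to 1, got {group_probs}")
    batch_cells = list(batch_cells)
    if sum(batch_cells) != n_cells:
        raise ValueError(f"batch_cells must sum to n_cells={n_cells}, got {sum(batch_cells)}")
    groups = rng.choice(group_probs.size, size=n_cells, p=group_probs) + 1
    batches = np.repeat(np.arange(1, len(batch_cells) + 1), batch_cells)
    return groups, batches


def simulate_batch_factors(n_genes, n_batches, batch_fac_loc, batch_fac_scale, rng) -> np.ndarray:
    """Per-batch multiplicative factors, genes x batches, applied to all genes."""
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if batch_fac_scale < 0:
        raise ValueError(f"batch_fac_scale must be >= 0, got {batch_fac_scale}")
    return rng.lognormal(batch_fac_loc, batch_fac_scale, size=(n_genes, n_batches))


def compute_cell_means(gene_means_with_factors, library_sizes) -> np.ndarray:
    """Rescale each column so its sum equals that cell's library size.

    ``out[i, j] = in[i, j] * L_j / sum_i in[i, j]`` — expected totals match
    the simulated library sizes exactly.
    """
    m = np.asarray(gene_means_with_factors, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    colsums = m.sum(axis=0)
    if np.any(colsums <= 0):
        bad = int(np.argmax(colsums <= 0))
        raise ValueError(f"column {bad} of the mean matrix has non-positive sum")
    return m * (lib / colsums)


def simulate_bcv(cell_means, bcv_common, bcv_df, rng) -> np.ndarray:
    """Biological coefficient of variation per gene and cell.

    One chi-squared(``bcv_df``) variate is drawn per gene, shared by all of a
    gene's cells; ``BCV[i, j] = (bcv_common + 1/sqrt(mean[i, j])) *
    sqrt(bcv_df / chi2_i)``.  The trend is decreasing in the mean, so lowly
    expressed genes are more variable.
    """
    if not bcv_df > 0:
        raise ValueError(f"bcv_df must be > 0, got {bcv_df}")
    if bcv_common < 0:
        raise ValueError(f"bcv_common must be >= 0, got {bcv_common}")
    cell_means = np.asarray(cell_means, dtype=float)
    q = rng.chisquare(bcv_df, size=cell_means.shape[0])
    scale = np.sqrt(bcv_df / q)[:, None]
    return (bcv_common + 1.0 / np.sqrt(cell_means)) * scale


def simulate_trended_means(cell_means, bcv, rng) -> np.ndarray:
    """Resample means from Gamma(1/BCV^2, rate 1/(BCV^2 * mean)).

    The draw has expectation equal to ``cell_means`` and coefficient of
    variation equal to ``bcv``, enforcing the mean-variance trend.
    """
    cell_means = np.asarray(cell_means, dtype=float)
    bcv = np.asarray(bcv, dtype=float)
    if cell_means.shape != bcv.shape:
        raise ValueError("cell_means and bcv must have the same shape")
    if np.any(cell_means <= 0) or np.any(bcv < 0):
        raise ValueError("cell_means must be positive and bcv non-negative")
    b = np.maximum(bcv, 1e-9)  # bcv == 0 degenerates to the mean itself
    shape = 1.0 / b**2
    return rng.gamma(shape, cell_means / shape)


def simulate_counts(trended_means, rng) -> np.ndarray:
    """Poisson counts with the trended means as rates."""
    lam = np.asarray(trended_means, dtype=float)
    if np.any(lam < 0):
        raise ValueError("trended means must be non-negative")
    return rng.poisson(lam)


def dropout_probability(log_expression, dropout_mid, dropout_shape) -> np.ndarray:
    """Logistic dropout probability ``1 / (1 + exp(k * (x - x0)))``.

    Equals 0.5 exactly at ``x == dropout_mid`` for any shape, and decreases
    with expression when ``dropout_shape > 0``.
    """
    x = np.asarray(log_expression, dtype=float)
    return expit(-dropout_shape * (x - dropout_mid))


def simulate_dropout(trended_means, dropout_mid, dropout_shape, rng,
                     counts_pre_dropout=None, by="cell"):
    """Zero out counts with an expression-dependent Bernoulli draw.

    ``by="cell"`` (default) evaluates the logistic on the natural log of each
    gene-and-cell trended mean; ``by="gene"`` uses one probability per gene,
    evaluated at the log of the gene's mean trended expression.

    Returns ``(dropout_prob, dropout_mask, counts)`` where ``mask`` is True
    for kept entries; ``counts`` is None unless ``counts_pre_dropout`` is
    given.
    """
    lam = np.asarray(trended_means, dtype=float)
    with np.errstate(divide="ignore"):
        if by == "cell":
            x = np.log(lam)
        elif by == "gene":
            x = np.broadcast_to(np.log(lam.mean(axis=1))[:, None], lam.shape)
        else:
            raise ValueError(f"by must be 'cell' or 'gene', got {by!r}")
    prob = dropout_probability(x, dropout_mid, dropout_shape)
    mask = rng.random(lam.shape) >= prob
    counts = None
    if counts_pre_dropout is not None:
        counts = np.asarray(counts_pre_dropout) * mask
    return prob, mask, counts


# ---------------------------------------------------------------------------
# differentiation paths


def brownian_bridge(n_steps, sigma, rng, start=0.0, end=0.0) -> np.ndarray:
    """A random walk over ``n_steps`` steps pinned to ``start`` and ``end``.

    Per-step innovations are Normal(0, sigma); the walk is tied down by
    subtracting the linear drift of its endpoint.  Returns ``n_steps + 1``
    values with the endpoints met exactly.
    """
    t = np.arange(n_steps + 1) / n_steps
    w = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sigma, size=n_steps))])
    bridge = w - t * w[-1]
    return start + (end - start) * t + bridge


def _smooth_bridges(bridges: np.ndarray, n_steps: int, n_knots: int = 10) -> np.ndarray:
    """Thin bridges to ~``n_knots`` evenly spaced knots and Akima-interpolate back."""
    idx = np.unique(np.round(np.linspace(0, n_steps, min(n_steps + 1, n_knots))).astype(int))
    if idx.size < 3:  # too short to smooth; keep the raw bridge
        return bridges
    interp = Akima1DInterpolator(idx, bridges[:, idx], axis=1)
    out = interp(np.arange(n_steps + 1))
    out[:, idx] = bridges[:, idx]  # knots (incl. endpoints) are exact
    return out


def simulate_path_factors(start_factors, end_factors, n_steps, nonlinear_prob,
                          sigma_fac, rng) -> np.ndarray:
    """Factor trajectory between two cell states, genes x (n_steps + 1).

    Linear genes interpolate log-factors linearly; with probability
    ``nonlinear_prob`` a gene instead follows the exponential of a smoothed
    Brownian bridge (per-step sd ``sigma_fac``) on the log scale, thinned to
    ~10 knots and Akima-interpolated.  Both endpoints are met exactly for
    every gene.
    """
    start = np.asarray(start_factors, dtype=float)
    end = np.asarray(end_factors, dtype=float)
    if start.shape != end.shape:
        raise ValueError("start_factors and end_factors must have equal length")
    if np.any(start <= 0) or np.any(end <= 0):
        raise ValueError("path factors must be strictly positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    log_s, log_e = np.log(start), np.log(end)
    t = np.arange(n_steps + 1) / n_steps
    traj = log_s[:, None] + (log_e - log_s)[:, None] * t[None, :]

    nonlinear = rng.random(start.size) < nonlinear_prob
    n_nl = int(nonlinear.sum())
    if n_nl and sigma_fac > 0:
        steps = rng.normal(0.0, sigma_fac, size=(n_nl, n_steps))
        w = np.concatenate([np.zeros((n_nl, 1)), np.cumsum(steps, axis=1)], axis=1)
        bridges = w - t[None, :] * w[:, -1:]
        bridges = _smooth_bridges(bridges, n_steps)
        traj[nonlinear] += bridges
    traj[:, 0] = log_s
    traj[:, -1] = log_e
    return np.exp(traj)


def assign_path_positions(n_cells, path_labels, path_skew, path_n_steps, rng):
    """Place each cell on a step of its path.

    The position fraction is Beta(2*skew, 2*(1 - skew)) — uniform at
    skew = 0.5, concentrated at the end as skew -> 1 — and is mapped to the
    nearest step.  Returns ``(steps, fractions)``.
    """
    path_labels = np.asarray(path_labels)
    skews = np.asarray(path_skew, dtype=float)
    n_steps = np.asarray(path_n_steps)
    if np.any((skews < 0) | (skews > 1)):
        raise ValueError(f"path_skew must be in [0, 1], got {skews}")
    frac = np.empty(n_cells)
    for p in range(skews.size):
        sel = path_labels == p + 1
        n_sel = int(sel.sum())
        s = skews[p]
        if s <= 0.0:
            frac[sel] = 0.0
        elif s >= 1.0:
            frac[sel] = 1.0
        else:
            frac[sel] = rng.beta(2.0 * s, 2.0 * (1.0 - s), size=n_sel)
    steps = np.rint(frac * n_steps[path_labels - 1]).astype(int)
    return steps, frac


def _resolve_path_endpoints(n_genes, path_from, change_factors):
    """Start/end factor vectors per path; a path starts at its origin's end."""
    n_paths = len(path_from)
    starts = [None] * n_paths
    ends = [None] * n_paths

    def resolve(k: int):
        if ends[k] is not None:
            return ends[k]
        origin = path_from[k]
        starts[k] = np.ones(n_genes) if origin == 0 else resolve(origin - 1).copy()
        ends[k] = starts[k] * change_factors[:, k]
        return ends[k]

    for k in range(n_paths):
        resolve(k)
    return starts, ends


# ---------------------------------------------------------------------------
# full pipeline


def splat_simulate(p: SplatParams, mode: str = "single", dropout_by: str = "cell") -> SimulationResult:
    """Run the full splat pipeline and return all truth layers.

    ``mode`` is one of "single" (one homogeneous population), "groups"
    (discrete cell types with log-normal DE factors) or "paths"
    (differentiation trajectories; ``group_probs`` doubles as the per-path
    probability vector).  Identical ``(params, mode)`` pairs give
    bit-identical results; the seed lives in ``p.seed``.
    """
    violations = validate_params(p)
    if violations:
        raise ValueError(
            "invalid parameters: " + "; ".join(str(v) for v in violations)
        )
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "paths" and len(p.group_probs) != len(p.path_from):
        raise ValueError(
            "paths mode needs one group_probs entry per path "
            f"({len(p.path_from)}), got {len(p.group_probs)}"
        )
    gen = _streams(p.seed)
    n_genes, n_cells = p.n_genes, p.n_cells

    raw_means = simulate_base_means(n_genes, p.mean_shape, p.mean_rate, gen["base_means"])
    base_means, out_flags, out_factors = apply_expression_outliers(
        raw_means, p.out_prob, p.out_loc, p.out_scale, gen["outliers"]
    )

    group_probs = p.group_probs if mode != "single" else [1.0]
    groups, batches = assign_cells(n_cells, group_probs, p.batch_cells, gen["group"])

    path_steps = np.zeros(n_cells, dtype=int)
    path_frac = np.zeros(n_cells)
    if mode == "single":
        de_factors = np.ones((n_genes, 1))
        cell_factors = np.ones((n_genes, n_cells))
    elif mode == "groups":
        de_factors = simulate_de_factors(
            n_genes, len(p.group_probs), p.de_prob, p.de_down_prob,
            p.de_loc, p.de_scale, gen["de"],
        )
        cell_factors = de_factors[:, groups - 1]
    else:  # paths
        n_paths = len(p.path_from)
        change = simulate_de_factors(
            n_genes, n_paths, p.de_prob, p.de_down_prob, p.de_loc, p.de_scale, gen["de"]
        )
        starts, ends = _resolve_path_endpoints(n_genes, p.path_from, change)
        trajectories = [
            simulate_path_factors(
                starts[k], ends[k], p.path_n_steps[k], p.path_nonlinear_prob,
                p.path_sigma_fac, gen["path"],
            )
            for k in range(n_paths)
        ]
        de_factors = np.column_stack([ends[k] for k in range(n_paths)])
        path_steps, path_frac = assign_path_positions(
            n_cells, groups, p.path_skew, p.path_n_steps, gen["group"]
        )
        cell_factors = np.empty((n_genes, n_cells))
        for j in range(n_cells):
            cell_factors[:, j] = trajectories[groups[j] - 1][:, path_steps[j]]

    n_batches = len(p.batch_cells)
    if n_batches > 1:
        batch_factors = simulate_batch_factors(
            n_genes, n_batches, p.batch_fac_loc, p.batch_fac_scale, gen["batch"]
        )
        cell_factors = cell_factors * batch_factors[:, batches - 1]
    else:
        batch_factors = np.ones((n_genes, 1))

    library_sizes = simulate_library_sizes(n_cells, p.lib_loc, p.lib_scale, gen["libsize"])
    cell_means = compute_cell_means(base_means[:, None] * cell_factors, library_sizes)
    bcv = simulate_bcv(cell_means, p.bcv_common, p.bcv_df, gen["bcv"])
    trended_means = simulate_trended_means(cell_means, bcv, gen["trend"])
    counts_pre = simulate_counts(trended_means, gen["poisson"])

    if p.dropout_present:
        dropout_prob, dropout_mask, counts = simulate_dropout(
            trended_means, p.dropout_mid, p.dropout_shape, gen["dropout"],
            counts_pre_dropout=counts_pre, by=dropout_by,
        )
    else:
        dropout_prob = np.zeros_like(trended_means)
        dropout_mask = np.ones(counts_pre.shape, dtype=bool)
        counts = counts_pre

    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"Cell{j + 1}" for j in range(n_cells)],
            "group": groups,
            "batch": batches,
            "path": groups if mode == "paths" else np.zeros(n_cells, dtype=int),
            "step": path_steps,
            "position": path_frac,
        }
    )
    return SimulationResult(
        counts=counts,
        counts_pre_dropout=counts_pre,
        base_means=base_means,
        outlier_flags=out_flags,
        outlier_factors=out_factors,
        library_sizes=library_sizes,
        de_factors=de_factors,
        batch_factors=batch_factors,
        cell_meta=cell_meta,
        cell_means=cell_means,
        bcv=bcv,
        trended_means=trended_means,
        dropout_prob=dropout_prob,
        dropout_mask=dropout_mask,
    )
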