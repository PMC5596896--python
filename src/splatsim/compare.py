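"""Summaries, sorted-difference tables, and MAD rankings of count datasets.

A :class:`DatasetSummary` holds the per-gene and per-cell statistics used to
judge how well a simulation reproduces a reference dataset: gene means and
variances on the log2(CPM + 1) scale, zero fractions and library sizes on raw
counts, and the paired mean-variance and mean-zeros relationships.

Differences against a reference are computed on sorted vectors (so the
comparison is between distributions, not gene identities); for the
relationship metrics both datasets' genes are sorted by mean expression and
the companion statistic compared.  The median absolute deviation (MAD) of
each difference vector is the comparison statistic, and simulations are
ranked per metric (rank 1 = most similar, ties share the minimum rank).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix

__all__ = [
    "METRICS",
    "DatasetSummary",
    "ComparisonResult",
    "summarize_dataset",
    "diff_from_reference",
    "mad_ranking",
    "compare_datasets",
    "plot_comparison",
]

#: The seven comparison metrics, in reporting order.
METRICS = (
    "mean",
    "variance",
    "library_size",
    "zeros_per_gene",
    "zeros_per_cell",
    "mean_variance",
    "mean_zeros",
)


@dataclass
class DatasetSummary:
    """Per-gene and per-cell summary statistics of one dataset."""

    name: str
    gene_mean: np.ndarray         # mean log2(CPM + 1) per gene
    gene_variance: np.ndarray     # variance of log2(CPM + 1) per gene
    gene_zero_fraction: np.ndarray
    cell_library_size: np.ndarray  # raw column totals
    cell_zero_fraction: np.ndarray

    @property
    def mean_variance_pairs(self) -> np.ndarray:
        return np.column_stack([self.gene_mean, self.gene_variance])

    @property
    def mean_zeros_pairs(self) -> np.ndarray:
        return np.column_stack([self.gene_mean, self.gene_zero_fraction])


@dataclass
class ComparisonResult:
    """Combined summaries plus (with a reference) difference/MAD/rank tables."""

    summaries: list
    reference_name: str | None = None
    combined: pd.DataFrame | None = None
    sorted_diff_tables: dict = field(default_factory=dict)
    mad_table: pd.DataFrame | None = None
    ranks: pd.DataFrame | None = None


def summarize_dataset(m, name: str, log_scale: bool = True) -> DatasetSummary:
    """Compute the summary statistics of one dataset.

    Gene means and variances are computed on log2(CPM + 1)-transformed counts
    by default (``log_scale=False`` keeps raw counts); zero fractions and
    library sizes always use the raw counts.  Gene means include cells with
    zero counts.
    """
    values = m.values if isinstance(m, CountMatrix) else np.asarray(m)
    if values.size == 0:
        raise ValueError("cannot summarize an empty matrix")
    values = values.astype(float)
    totals = values.sum(axis=0)
    if log_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            cpm = np.where(totals > 0, values / totals * 1e6, 0.0)
        expr = np.log2(cpm + 1.0)
    else:
        expr = values
    return DatasetSummary(
        name=name,
        gene_mean=expr.mean(axis=1),
        gene_variance=expr.var(axis=1, ddof=1),
        gene_zero_fraction=(values == 0).mean(axis=1),
        cell_library_size=totals,
        cell_zero_fraction=(values == 0).mean(axis=0),
    )


def _common_sorted(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort both vectors; map the longer onto the shorter's quantile grid."""
    a, b = np.sort(a), np.sort(b)
    if a.size == b.size:
        return a, b
    n = min(a.size, b.size)
    grid = np.linspace(0.0, 1.0, n)
    qa = np.quantile(a, grid) if a.size != n else a
    qb = np.quantile(b, grid) if b.size != n else b
    return qa, qb


def _companion_by_mean(s: DatasetSummary, metric: str) -> np.ndarray:
    companion = s.gene_variance if metric == "mean_variance" else s.gene_zero_fraction
    return companion[np.argsort(s.gene_mean, kind="stable")]


def diff_from_reference(ref: DatasetSummary, other: DatasetSummary) -> dict:
    """Per-metric sorted difference vectors, simulation minus reference.

    Basic metrics compare sorted value vectors.  Relationship metrics
    (``mean_variance``, ``mean_zeros``) sort both datasets' genes by mean
    expression and difference the companion statistic.  Unequal lengths are
    reconciled on a common quantile grid.
    """
    basic = {
        "mean": ("gene_mean", "gene_mean"),
        "variance": ("gene_variance", "gene_variance"),
        "library_size": ("cell_library_size", "cell_library_size"),
        "zeros_per_gene": ("gene_zero_fraction", "gene_zero_fraction"),
        "zeros_per_cell": ("cell_zero_fraction", "cell_zero_fraction"),
    }
    diffs: dict = {}
    for metric, (ra, oa) in basic.items():
        r, o = _common_sorted(getattr(ref, ra), getattr(other, oa))
        diffs[metric] = o - r
    for metric in ("mean_variance", "mean_zeros"):
        r = _companion_by_mean(ref, metric)
        o = _companion_by_mean(other, metric)
        n = min(r.size, o.size)
        if r.size != o.size:  # trim tails of the mean-ordering to common length
            r, o = r[:n], o[:n]
        diffs[metric] = o - r
    return diffs


def mad_ranking(ref: DatasetSummary, sims: list) -> ComparisonResult:
    """MAD table and per-metric ranks of simulations against a reference.

    MAD = median absolute sorted difference.  Ranks ascend with MAD (rank 1 =
    most similar to the reference); ties share the minimum rank.
    """
    if not sims:
        raise ValueError("need at least one simulation summary to rank")
    diff_tables = {s.name: diff_from_reference(ref, s) for s in sims}
    mad = pd.DataFrame(
        {s.name: {m: float(np.median(np.abs(diff_tables[s.name][m]))) for m in METRICS}
         for s in sims},
    ).reindex(index=list(METRICS))
    ranks = mad.apply(lambda row: rankdata(row, method="min"), axis=1, result_type="broadcast")
    ranks = ranks.astype(int)
    return ComparisonResult(
        summaries=[ref] + list(sims),
        reference_name=ref.name,
        combined=_combined_table([ref] + list(sims)),
        sorted_diff_tables=diff_tables,
        mad_table=mad,
        ranks=ranks,
    )


def _combined_table(summaries: list) -> pd.DataFrame:
    """Long-form table of all distribution statistics, for plotting/export."""
    rows = []
    for s in summaries:
        for stat, values in (
            ("mean", s.gene_mean),
            ("variance", s.gene_variance),
            ("zeros_per_gene", s.gene_zero_fraction),
            ("library_size", s.cell_library_size),
            ("zeros_per_cell", s.cell_zero_fraction),
        ):
            rows.append(pd.DataFrame({"dataset": s.name, "statistic": stat, "value": values}))
    return pd.concat(rows, ignore_index=True)


def compare_datasets(summaries: list, reference_name: str | None = None) -> ComparisonResult:
    """Compare several dataset summaries, optionally against a reference.

    Without a reference only the combined distribution table is produced;
    with one, sorted-difference tables, the MAD table and per-metric ranks of
    every other dataset are added.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 dataset summaries to compare")
    names = [s.name for s in summaries]
    if reference_name is None:
        return ComparisonResult(summaries=list(summaries), combined=_combined_table(summaries))
    if reference_name not in names:
        raise ValueError(f"reference {reference_name!r} not among datasets {names}")
    ref = summaries[names.index(reference_name)]
    sims = [s for s in summaries if s.name != reference_name]
    return mad_ranking(ref, sims)


def plot_comparison(result: ComparisonResult, outdir) -> list:
    """Write diagnostic panels (distribution boxplots, relationship scatters,
    and — when a reference is present — sorted-difference boxplots) as PNGs.

    Returns the list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    combined = result.combined
    if combined is None:
        combined = _combined_table(result.summaries)
    stats_order = ["mean", "variance", "library_size", "zeros_per_gene", "zeros_per_cell"]
    fig, axes = plt.subplots(1, len(stats_order), figsize=(4 * len(stats_order), 4))
    for ax, stat in zip(axes, stats_order):
        sub = combined[combined["statistic"] == stat]
        groups = [g["value"].to_numpy() for _, g in sub.groupby("dataset", sort=False)]
        labels = [n for n, _ in sub.groupby("dataset", sort=False)]
        ax.boxplot(groups, tick_labels=labels)
        ax.set_title(stat)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    path = outdir / "distributions.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(path)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for s in result.summaries:
        axes[0].scatter(s.gene_mean, s.gene_variance, s=3, alpha=0.4, label=s.name)
        axes[1].scatter(s.gene_mean, s.gene_zero_fraction, s=3, alpha=0.4, label=s.name)
    axes[0].set_xlabel("mean log2(CPM+1)"); axes[0].set_ylabel("variance")
    axes[1].set_xlabel("mean log2(CPM+1)"); axes[1].set_ylabel("zero fraction")
    axes[0].legend(markerscale=3, fontsize=7)
    fig.tight_layout()
    path = outdir / "relationships.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    written.append(path)

    if result.sorted_diff_tables:
        fig, axes = plt.subplots(1, len(METRICS), figsize=(3.2 * len(METRICS), 4))
        for ax, metric in zip(axes, METRICS):
            names = list(result.sorted_diff_tables)
            ax.boxplot([result.sorted_diff_tables[n][metric] for n in names],
                       tick_labels=names)
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.set_title(metric)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        path = outdir / "differences.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
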