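"""Count-matrix containers, readers/writers, and deterministic test fixtures.

Counts travel as Matrix Market coordinate files (1-based indices, integer
field) with ``genes.tsv`` / ``cells.tsv`` sidecars, or as dense TSV with gene
rows and cell columns.  Indexing is 0-based everywhere inside the package;
the 1-based convention is confined to the MTX files themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from . import splat as _splat
from .params import SplatParams, update_params, default_params

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "write_simulation",
    "result_to_count_matrix",
    "Fixture",
    "make_fixture",
]


@dataclass
class CountMatrix:
    """A genes x cells matrix of non-negative integer counts with identifiers."""

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            as_int = self.values.astype(np.int64)
            if not np.array_equal(as_int, self.values):
                bad = np.argwhere(as_int != self.values)[0]
                raise ValueError(
                    f"non-integer count at gene {bad[0]}, cell {bad[1]}: "
                    f"{self.values[bad[0], bad[1]]!r}"
                )
            self.values = as_int
        if self.values.size and self.values.min() < 0:
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative count at gene {bad[0]}, cell {bad[1]}: "
                f"{self.values[bad[0], bad[1]]}"
            )
        if not self.gene_ids:
            self.gene_ids = [f"Gene{i + 1}" for i in range(self.values.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"Cell{j + 1}" for j in range(self.values.shape[1])]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} gene rows"
            )
        if len(self.cell_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[1]} cell columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids contain duplicates")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids contain duplicates")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def result_to_count_matrix(result: _splat.SimulationResult) -> CountMatrix:
    """Wrap a simulation's final counts as a :class:`CountMatrix`."""
    return CountMatrix(result.counts, result.gene_ids, result.cell_ids)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format='mtx' or 'tsv'")


def _read_ids(path: Path, what: str, n: int) -> list:
    ids = pd.read_csv(path, sep="\t", header=None)[0].astype(str).tolist()
    if len(ids) != n:
        raise ValueError(f"{path} lists {len(ids)} {what} but the matrix has {n}")
    return ids


def read_counts(path, format: str | None = None, genes=None, cells=None) -> CountMatrix:
    """Read a count matrix from MTX (+ sidecars) or dense TSV.

    For MTX the gene/cell identifier sidecars default to ``genes.tsv`` and
    ``cells.tsv`` next to the matrix file; missing sidecars fall back to
    generated identifiers.  Negative or non-integer entries are rejected with
    their coordinates.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_path = Path(genes) if genes else path.parent / "genes.tsv"
        cell_path = Path(cells) if cells else path.parent / "cells.tsv"
        gene_ids = _read_ids(gene_path, "genes", dense.shape[0]) if gene_path.exists() else []
        cell_ids = _read_ids(cell_path, "cells", dense.shape[1]) if cell_path.exists() else []
        return CountMatrix(dense, gene_ids, cell_ids)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(df.to_numpy(), df.index.tolist(), df.columns.tolist())
    raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")


def write_counts(m: CountMatrix, path, format: str | None = None) -> Path:
    """Write a count matrix as MTX (+ ``genes.tsv``/``cells.tsv``) or TSV."""
    if m.values.size == 0:
        raise ValueError("refusing to write an empty count matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        coo = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(path, coo, field="integer")
        pd.Series(m.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(path.parent / "cells.tsv", sep="\t", header=False, index=False)
    elif fmt == "tsv":
        m.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'tsv'")
    return path


def write_simulation(result: _splat.SimulationResult, outdir, format: str = "mtx") -> dict:
    """Write a simulation's counts plus its truth layers to ``outdir``.

    Writes the final counts (``counts.mtx`` or ``counts.tsv``), per-cell
    metadata (``cell_meta.tsv`` with group/batch/path/step plus the realized
    library size), and per-gene truth (``gene_info.tsv`` with base means,
    outlier flags/factors and DE factors).  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm = result_to_count_matrix(result)
    counts_path = write_counts(cm, outdir / f"counts.{format}", format=format)

    meta = result.cell_meta.copy()
    meta["library_size"] = result.library_sizes
    meta_path = outdir / "cell_meta.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)

    gene_info = pd.DataFrame({"gene_id": cm.gene_ids, "base_mean": result.base_means,
                              "outlier": result.outlier_flags,
                              "outlier_factor": result.outlier_factors})
    for g in range(result.de_factors.shape[1]):
        gene_info[f"de_factor_{g + 1}"] = result.de_factors[:, g]
    gene_path = outdir / "gene_info.tsv"
    gene_info.to_csv(gene_path, sep="\t", index=False)
    return {"counts": counts_path, "cell_meta": meta_path, "gene_info": gene_path}


# ---------------------------------------------------------------------------
# fixtures


@dataclass
class Fixture:
    """A small deterministic dataset for tests, fully determined by (recipe, seed)."""

    counts: CountMatrix
    descriptor: str
    cell_meta: pd.DataFrame | None = None
    result: _splat.SimulationResult | None = None


RECIPES = ("tiny-uniform", "tiny-splat", "tiny-with-groups")


def _tiny_params(seed: int, **overrides) -> SplatParams:
    base = dict(n_genes=50, n_cells=20, seed=seed, lib_loc=6.0, batch_cells=[20])
    base.update(overrides)
    return update_params(default_params("splat"), base)


def make_fixture(recipe: str, seed: int = 0) -> Fixture:
    """Build one of the named small test datasets.

    "tiny-uniform" is a 50 x 20 Poisson matrix with one all-zero gene and no
    zero-total cells; "tiny-splat" and "tiny-with-groups" are reduced-size
    runs of the full simulation (the latter guaranteed to contain at least
    two distinct group labels).
    """
    if recipe == "tiny-uniform":
        rng = np.random.default_rng(seed)
        values = rng.poisson(3.0, size=(50, 20))
        values[7, :] = 0  # guaranteed all-zero gene
        empty = values.sum(axis=0) == 0
        values[0, empty] = 1  # no zero-total cells
        return Fixture(CountMatrix(values), f"tiny-uniform(seed={seed})")
    if recipe == "tiny-splat":
        result = _splat.splat_simulate(_tiny_params(seed), mode="single")
        return Fixture(result_to_count_matrix(result), f"tiny-splat(seed={seed})",
                       cell_meta=result.cell_meta, result=result)
    if recipe == "tiny-with-groups":
        # re-seed deterministically until both groups appear (~never loops twice)
        for offset in range(1000):
            p = _tiny_params(seed + offset, group_probs=[0.5, 0.5],
                             de_prob=[0.3, 0.3], de_down_prob=[0.5, 0.5],
                             de_loc=[0.5, 0.5], de_scale=[0.4, 0.4])
            result = _splat.splat_simulate(p, mode="groups")
            if result.cell_meta["group"].nunique() >= 2:
                return Fixture(result_to_count_matrix(result),
                               f"tiny-with-groups(seed={seed})",
                               cell_meta=result.cell_meta, result=result)
        raise RuntimeError("could not generate a two-group fixture")  # pragma: no cover
    raise ValueError(f"unknown recipe {recipe!r}; expected one of {RECIPES}")
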