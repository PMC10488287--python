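"""Quality control, normalization, clustering, and cell-count matching."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix


class EmptyResultError(RuntimeError):
    """All cells (or genes) removed by a filter; names the failing threshold."""


@dataclass
class QCConfig:
    """Cell- and gene-level quality-control thresholds.

    Defaults are conventional and user-overridable; every applied filter is
    appended to the matrix ``log``.
    """

    min_genes_per_cell: int = 200
    min_counts_per_cell: int = 500
    max_mito_fraction: float = 0.2
    min_cells_per_gene: int = 3
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_counts_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must lie in [0, 1]")


def qc_filter(m: ExpressionMatrix, cfg: QCConfig | None = None) -> ExpressionMatrix:
    """Filter low-quality cells, then low-coverage genes.

    A retained cell expresses at least ``min_genes_per_cell`` genes, holds at
    least ``min_counts_per_cell`` total counts, and has a mitochondrial count
    fraction at most ``max_mito_fraction`` (genes whose id starts with
    ``mito_prefix``, case-insensitive). A retained gene is expressed in at
    least ``min_cells_per_gene`` of the retained cells. Cells are filtered
    before genes, so the operation is deterministic and idempotent.
    """
    cfg = cfg or QCConfig()
    counts = m.counts

    genes_per_cell = (counts > 0).sum(axis=0)
    counts_per_cell = counts.sum(axis=0)
    prefix = cfg.mito_prefix.lower()
    mito_rows = np.array([g.lower().startswith(prefix) for g in m.gene_ids])
    if mito_rows.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(
                counts_per_cell > 0,
                counts[mito_rows, :].sum(axis=0) / np.maximum(counts_per_cell, 1e-300),
                0.0,
            )
    else:
        mito_frac = np.zeros(m.n_cells)

    cell_masks = {
        f"min_genes_per_cell={cfg.min_genes_per_cell}": genes_per_cell >= cfg.min_genes_per_cell,
        f"min_counts_per_cell={cfg.min_counts_per_cell}": counts_per_cell >= cfg.min_counts_per_cell,
        f"max_mito_fraction={cfg.max_mito_fraction}": mito_frac <= cfg.max_mito_fraction,
    }
    keep_cells = np.ones(m.n_cells, dtype=bool)
    for mask in cell_masks.values():
        keep_cells &= mask
    if not keep_cells.any():
        for name, mask in cell_masks.items():
            if not mask.any():
                raise EmptyResultError(f"all cells removed by threshold {name}")
        raise EmptyResultError(
            "all cells removed by combined QC thresholds: "
            + ", ".join(cell_masks.keys())
        )

    out = m.subset_cells(np.flatnonzero(keep_cells))

    cells_per_gene = (out.counts > 0).sum(axis=1)
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    if not keep_genes.any():
        raise EmptyResultError(
            f"all genes removed by threshold min_cells_per_gene={cfg.min_cells_per_gene}"
        )
    out = out.subset_genes([g for g, k in zip(out.gene_ids, keep_genes) if k])
    out.log = m.log + [
        f"qc_filter: {m.n_cells - out.n_cells} cells and {m.n_genes - out.n_genes} genes removed ({cfg})"
    ]
    return out


def normalize(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Total-count scale every cell to ``target_sum``, then log1p."""
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = m.counts.sum(axis=0)
    if np.any(totals == 0):
        zero = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise EmptyResultError(
            f"cells with zero total counts (e.g. {zero}); run qc_filter first"
        )
    out = m.copy()
    out.counts = np.log1p(m.counts / totals[None, :] * target_sum)
    out.log = m.log + [f"normalize: target_sum={target_sum}, log1p"]
    return out


def _as_anndata(m: ExpressionMatrix):
    import anndata as ad

    adata = ad.AnnData(X=m.counts.T.copy())
    adata.obs_names = list(m.cell_ids)
    adata.var_names = list(m.gene_ids)
    return adata


def cluster_cells(
    m: ExpressionMatrix,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Leiden community detection on a kNN graph of cells.

    Returns an integer cluster label per cell. Deterministic given ``seed``.
    """
    import scanpy as sc

    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    n_neighbors = min(n_neighbors, m.n_cells - 1)
    adata = _as_anndata(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            key_added="leiden",
        )
    return adata.obs["leiden"].astype(int).to_numpy()


def subsample_cells(m: ExpressionMatrix, n_target: int, seed: int = 0) -> ExpressionMatrix:
    """Uniformly subsample ``n_target`` cells without replacement.

    The retained columns keep their original relative order, so an already
    pseudotime-ordered matrix stays ordered.
    """
    if n_target > m.n_cells:
        raise ValueError(f"n_target={n_target} exceeds cell count {m.n_cells}")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m.n_cells, size=n_target, replace=False))
    out = m.subset_cells(idx)
    out.log = m.log + [f"subsample_cells: {n_target}/{m.n_cells} (seed={seed})"]
    return out
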