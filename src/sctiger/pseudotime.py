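"""Trajectory ordering of cells so expression can be read as a time series.

Cells are embedded with a kNN graph + diffusion map, a partition-based graph
abstraction is computed over the clusters, and a diffusion pseudotime is
assigned from a root cell. Disconnected neighbor graphs are handled per
connected component (largest first), with later components offset so the
pseudotime stays non-decreasing along the returned order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse.csgraph

from .matrix import ExpressionMatrix
from .preprocess import _as_anndata, cluster_cells


@dataclass
class PseudotimeOrdering:
    """A permutation of cell indices plus the per-cell pseudotime.

    ``order[k]`` is the input index of the cell at trajectory position ``k``;
    ``pseudotime`` is indexed by input cell index and is non-decreasing when
    read along ``order``.
    """

    order: np.ndarray
    pseudotime: np.ndarray
    clusters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        n = len(self.pseudotime)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order is not a permutation of all cells")
        pt = self.pseudotime[self.order]
        if np.any(np.diff(pt) < -1e-12):
            raise ValueError("pseudotime not non-decreasing along order")


def _component_order(m: ExpressionMatrix, idx: np.ndarray, seed: int, root: str | None) -> np.ndarray:
    """Pseudotime values for the cells of one connected component."""
    import scanpy as sc

    n = len(idx)
    if n <= 2:
        return np.arange(n, dtype=float)
    sub = m.subset_cells(idx)
    adata = _as_anndata(sub)
    n_neighbors = min(15, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)
        try:
            sc.tl.leiden(adata, random_state=seed, flavor="leidenalg", key_added="leiden")
        except Exception:
            adata.obs["leiden"] = "0"
        adata.obs["leiden"] = adata.obs["leiden"].astype("category")
        sc.tl.paga(adata, groups="leiden")
        sc.tl.diffmap(adata, n_comps=min(15, n - 1))

        dc1 = adata.obsm["X_diffmap"][:, 1] if adata.obsm["X_diffmap"].shape[1] > 1 else adata.obsm["X_diffmap"][:, 0]
        if root is not None and root in sub.cell_ids:
            iroot = sub.cell_ids.index(root)
        else:
            # trajectory endpoint: the globally most extreme first diffusion
            # component (a cluster-restricted choice can land mid-trajectory
            # and fold the ordering)
            iroot = int(np.argmax(np.abs(dc1 - np.median(dc1))))
        adata.uns["iroot"] = iroot
        sc.tl.dpt(adata)
    pt = np.asarray(adata.obs["dpt_pseudotime"], dtype=float)
    # dpt can emit inf for cells unreachable despite graph connectivity; fall
    # back to their DC1 rank pushed past the finite range
    bad = ~np.isfinite(pt)
    if bad.any():
        hi = pt[~bad].max() if (~bad).any() else 0.0
        ranks = np.argsort(np.argsort(dc1[bad]))
        pt[bad] = hi + 1.0 + ranks
    return pt


def order_cells(
    m: ExpressionMatrix,
    clusters: np.ndarray | None = None,
    root: str | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
) -> PseudotimeOrdering:
    """Order the cells of a normalized matrix along an inferred trajectory.

    Parameters
    ----------
    m
        Normalized genes-x-cells matrix.
    clusters
        Optional precomputed integer labels; computed with Leiden when absent.
    root
        Optional cell id to use as trajectory root. Default: the cell with
        the most extreme first diffusion component within the largest cluster.
    seed
        Random state threaded through neighbors/Leiden/diffmap.
    """
    import scanpy as sc

    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to order")

    if m.n_cells <= 3:
        pt = np.arange(m.n_cells, dtype=float)
        order = np.arange(m.n_cells)
        return PseudotimeOrdering(order=order, pseudotime=pt, clusters=clusters)

    adata = _as_anndata(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, m.n_cells - 1), random_state=seed)
    n_comp, comp_labels = scipy.sparse.csgraph.connected_components(
        adata.obsp["connectivities"], directed=False
    )
    if n_comp > 1:
        warnings.warn(
            f"neighbor graph has {n_comp} connected components; ordering each "
            "separately, largest first",
            stacklevel=2,
        )
    comp_ids = sorted(range(n_comp), key=lambda c: (-np.sum(comp_labels == c), c))

    pseudotime = np.zeros(m.n_cells)
    offset = 0.0
    order_parts = []
    for c in comp_ids:
        idx = np.flatnonzero(comp_labels == c)
        pt_local = _component_order(m, idx, seed, root)
        pseudotime[idx] = pt_local + offset
        # stable tie-break on original input index
        part = idx[np.lexsort((idx, pt_local))]
        order_parts.append(part)
        offset = pseudotime[idx].max() + 1.0
    order = np.concatenate(order_parts)

    if clusters is None:
        clusters = cluster_cells(m, seed=seed) if m.n_cells > 4 else np.zeros(m.n_cells, dtype=int)
    return PseudotimeOrdering(order=order, pseudotime=pseudotime, clusters=np.asarray(clusters))


def apply_ordering(m: ExpressionMatrix, ordering: PseudotimeOrdering) -> ExpressionMatrix:
    """Permute the matrix columns into pseudotime order."""
    if len(ordering.order) != m.n_cells:
        raise ValueError(
            f"ordering covers {len(ordering.order)} cells, matrix has {m.n_cells}"
        )
    return m.subset_cells(ordering.order)


def pseudotime_table(m: ExpressionMatrix, ordering: PseudotimeOrdering):
    """Per-cell (cell_id, cluster, pseudotime) table for inspection."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "cluster": ordering.clusters if ordering.clusters is not None else -1,
            "pseudotime": ordering.pseudotime,
        }
    )
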