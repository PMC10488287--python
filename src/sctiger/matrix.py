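"""Expression matrix container and readers.

The canonical in-memory layout is genes x cells (rows x columns), matching
the dense CSV/TSV on-disk convention (first column = gene ids, header row =
cell ids). 10x-style MTX triplets with genes/features and barcodes sidecars
are densified on load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MatrixFormatError(ValueError):
    """Raised when an on-disk matrix and its sidecars disagree."""


@dataclass
class ExpressionMatrix:
    """A genes-x-cells expression matrix with row/column identifiers.

    Parameters
    ----------
    counts
        Non-negative ``(n_genes, n_cells)`` array. Raw counts or normalized
        values depending on pipeline stage.
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell identifiers (barcodes), one per column.
    condition
        Free-form condition label (e.g. ``"case"``/``"control"``).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    condition: str = ""
    log: list[str] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise MatrixFormatError(f"counts must be 2-D, got shape {self.counts.shape}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise MatrixFormatError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[0]} rows"
            )
        if len(self.cell_ids) != self.counts.shape[1]:
            raise MatrixFormatError(
                f"{len(self.cell_ids)} cell ids for {self.counts.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixFormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixFormatError("cell ids are not unique")
        if np.any(self.counts < 0):
            raise MatrixFormatError("negative entries in expression matrix")
        if not np.all(np.isfinite(self.counts)):
            raise MatrixFormatError("non-finite entries in expression matrix")

    # -- convenience -------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return replace(self, counts=self.counts[idx, :], gene_ids=list(genes))

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            counts=self.counts[:, idx],
            cell_ids=[self.cell_ids[i] for i in idx],
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(self, counts=self.counts.copy())

    def to_csv(self, path: str | os.PathLike, sep: str = ",") -> None:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)
        df.to_csv(path, sep=sep)


def _dedupe(names: list[str]) -> list[str]:
    """Suffix duplicate names with .1, .2, ... preserving first occurrence."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def _read_sidecar(path: str) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    # 10x features.tsv has (id, symbol, type); prefer the symbol column when present
    col = 1 if df.shape[1] > 1 else 0
    return df.iloc[:, col].tolist()


def load_matrix(
    path: str | os.PathLike,
    format: str | None = None,
    condition: str = "",
) -> ExpressionMatrix:
    """Load an expression matrix from MTX (with sidecars) or dense CSV/TSV.

    ``path`` is either a dense text matrix file, a ``matrix.mtx`` file, or a
    directory containing ``matrix.mtx`` plus ``genes.tsv``/``features.tsv``
    and ``barcodes.tsv``. Duplicate gene symbols are deduplicated with a
    numeric suffix so downstream gene lookups stay unambiguous.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    if format is None:
        if os.path.isdir(path) or path.endswith(".mtx"):
            format = "mtx"
        elif path.endswith(".tsv") or path.endswith(".txt"):
            format = "tsv"
        else:
            format = "csv"
    format = format.lower()

    if format == "mtx":
        mtx_path = os.path.join(path, "matrix.mtx") if os.path.isdir(path) else path
        base = os.path.dirname(mtx_path)
        if not os.path.exists(mtx_path):
            raise FileNotFoundError(mtx_path)
        genes_path = None
        for name in ("genes.tsv", "features.tsv"):
            cand = os.path.join(base, name)
            if os.path.exists(cand):
                genes_path = cand
                break
        barcodes_path = os.path.join(base, "barcodes.tsv")
        if genes_path is None or not os.path.exists(barcodes_path):
            raise FileNotFoundError(
                f"MTX sidecars (genes.tsv/features.tsv + barcodes.tsv) missing in {base}"
            )
        mat = scipy.io.mmread(mtx_path)
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
        )
        genes = _read_sidecar(genes_path)
        barcodes = _read_sidecar(barcodes_path)
        if len(genes) != counts.shape[0]:
            raise MatrixFormatError(
                f"genes sidecar has {len(genes)} entries, matrix has {counts.shape[0]} rows"
            )
        if len(barcodes) != counts.shape[1]:
            raise MatrixFormatError(
                f"barcodes sidecar has {len(barcodes)} entries, matrix has "
                f"{counts.shape[1]} columns"
            )
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy(dtype=np.float64)
        genes = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown format {format!r}")

    return ExpressionMatrix(
        counts=counts,
        gene_ids=_dedupe(genes),
        cell_ids=_dedupe(barcodes),
        condition=condition,
    )
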