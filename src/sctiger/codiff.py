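"""Co-differential expression: the case-minus-control series per gene.

After both conditions are pseudotime-ordered and cell-count matched, each
gene contributes one series ``x_i[t] = case_i[t] - control_i[t]``. Pairs of
genes that co-vary within a condition but whose co-differential series are
unrelated carry no signal here, which is exactly the false-positive filter
the construction provides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoDiffMatrix:
    """N gene series of common length T (pseudotime positions)."""

    X: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.gene_ids):
            raise ValueError("X must be (n_genes, T) matching gene_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in co-differential matrix") from None

    def subset(self, genes: list[str]) -> "CoDiffMatrix":
        idx = [self.gene_index(g) for g in genes]
        return CoDiffMatrix(X=self.X[idx, :], gene_ids=list(genes))


@dataclass
class CandidateSet:
    """Top-|r| screened candidate regulators/targets for one gene of interest."""

    goi: str
    candidates: list[tuple[str, float]]  # (gene, Pearson r vs goi series)

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.candidates]


def dropout_fraction(
    case: ExpressionMatrix, control: ExpressionMatrix, gene: str
) -> float:
    """Fraction of zero entries for ``gene`` pooled across both matrices."""
    i, j = case.gene_index(gene), control.gene_index(gene)
    zeros = int((case.counts[i, :] == 0).sum() + (control.counts[j, :] == 0).sum())
    return zeros / (case.n_cells + control.n_cells)


def filter_genes_by_dropout(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    max_dropout: float = 0.9,
    genes_of_interest: list[str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Keep genes whose pooled zero fraction is at most ``max_dropout``.

    Operates on the shared gene universe; gene order of ``case`` preserved.
    Raises if a gene of interest would be removed, naming the offending gene
    and its dropout fraction.
    """
    shared = [g for g in case.gene_ids if g in set(control.gene_ids)]
    if not shared:
        raise ValueError("case and control share no genes")
    case_s = case.subset_genes(shared)
    control_s = control.subset_genes(shared)
    n_total = case_s.n_cells + control_s.n_cells
    zeros = (case_s.counts == 0).sum(axis=1) + (control_s.counts == 0).sum(axis=1)
    frac = zeros / n_total
    keep = frac <= max_dropout
    if genes_of_interest:
        for goi in genes_of_interest:
            if goi not in shared:
                raise KeyError(f"gene of interest {goi!r} absent from shared gene set")
            k = shared.index(goi)
            if not keep[k]:
                raise ValueError(
                    f"gene of interest {goi!r} removed by dropout filter "
                    f"(fraction {frac[k]:.3f} > max_dropout {max_dropout})"
                )
    kept = [g for g, k in zip(shared, keep) if k]
    return case_s.subset_genes(kept), control_s.subset_genes(kept)


def compute_codiff(
    case_ordered: ExpressionMatrix, control_ordered: ExpressionMatrix
) -> CoDiffMatrix:
    """Position-wise case-minus-control differential series per gene."""
    if case_ordered.gene_ids != control_ordered.gene_ids:
        raise ValueError("case and control gene sets/orders differ; align genes first")
    if case_ordered.n_cells != control_ordered.n_cells:
        raise ValueError(
            f"unequal cell counts ({case_ordered.n_cells} vs "
            f"{control_ordered.n_cells}); subsample the larger condition first"
        )
    return CoDiffMatrix(
        X=case_ordered.counts - control_ordered.counts,
        gene_ids=list(case_ordered.gene_ids),
    )


def _pearson_to_row(X: np.ndarray, i: int) -> np.ndarray:
    """Pearson r of every row of X against row i (NaN for zero-variance rows)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Xc[i]) / (X.shape[1] * sd * sd[i])
    r[sd == 0] = np.nan
    return r


def select_candidates(X: CoDiffMatrix, goi: str, k: int = 100) -> CandidateSet:
    """Screen the k genes with the largest |Pearson r| to the goi series.

    Absolute correlation is used so that strongly anti-correlated (candidate
    repressive) genes survive screening. Zero-variance genes are excluded;
    ties are broken by gene id order.
    """
    i = X.gene_index(goi)
    if np.std(X.X[i]) == 0:
        raise ValueError(f"gene {goi!r} has no co-differential signal (zero variance)")
    r = _pearson_to_row(X.X, i)
    scored = [
        (X.gene_ids[j], float(r[j]))
        for j in range(X.n_genes)
        if j != i and np.isfinite(r[j])
    ]
    scored.sort(key=lambda t: (-abs(t[1]), t[0]))
    return CandidateSet(goi=goi, candidates=scored[:k])


def regulation_sign(x_i: np.ndarray, x_j: np.ndarray) -> str:
    """'positive' iff the Pearson correlation of the two series is >= 0.

    Positive regulation corresponds to positively correlated co-differential
    series; r == 0 exactly defaults to 'positive' (logged).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if np.std(x_i) == 0 or np.std(x_j) == 0:
        raise ValueError("regulation_sign requires both series to have variance")
    r = float(np.corrcoef(x_i, x_j)[0, 1])
    if r == 0.0:
        logger.info("exactly zero correlation; defaulting to positive sign")
    return "positive" if r >= 0 else "negative"
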