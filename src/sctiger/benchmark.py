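"""Benchmark protocol: single-dataset edge recovery against a reference.

Consumes BEELINE-style directories (``ExpressionData.csv`` genes x cells +
``refNetwork.csv`` with Gene1/Gene2/Type columns). Because no paired control
exists, the co-differential subtraction and correlation screening are
bypassed: the pseudotime-ordered expression matrix feeds the causal core
directly. Predicted and reference edge sets are canonicalized (direction,
sign and self-loops disregarded) before computing precision, recall, F1 and
specificity over the unordered non-self pair universe.
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .causal import ADDSTCNConfig, discover
from .codiff import CoDiffMatrix
from .matrix import ExpressionMatrix, MatrixFormatError
from .preprocess import subsample_cells
from .pseudotime import apply_ordering, order_cells
from .significance import fit_count_model, shuffle_within_genes

Pair = frozenset


@dataclass
class ReferenceNetwork:
    edges: set[frozenset]  # canonical unordered pairs
    genes: list[str]

    def __post_init__(self) -> None:
        universe = set(self.genes)
        for pair in self.edges:
            if not set(pair) <= universe:
                raise ValueError(f"reference edge {set(pair)} outside gene universe")


@dataclass
class BenchmarkResult:
    precision: float
    recall: float
    specificity: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: list[str] = field(default_factory=list)


def load_beeline(directory: str | os.PathLike) -> tuple[ExpressionMatrix, ReferenceNetwork]:
    """Parse ExpressionData.csv + refNetwork.csv from a dataset directory."""
    directory = os.fspath(directory)
    expr_path = os.path.join(directory, "ExpressionData.csv")
    ref_path = os.path.join(directory, "refNetwork.csv")
    for p in (expr_path, ref_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    df = pd.read_csv(expr_path, index_col=0)
    m = ExpressionMatrix(
        counts=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
    )
    if m.n_cells != 200:
        warnings.warn(f"expected 200 cells, found {m.n_cells}", stacklevel=2)
    ref_df = pd.read_csv(ref_path)
    cols = {c.lower(): c for c in ref_df.columns}
    if "gene1" not in cols or "gene2" not in cols:
        raise MatrixFormatError(
            f"refNetwork.csv must have Gene1/Gene2 columns, found {list(ref_df.columns)}"
        )
    raw = {
        (str(a), str(b))
        for a, b in zip(ref_df[cols["gene1"]], ref_df[cols["gene2"]])
    }
    ref = ReferenceNetwork(edges=canonicalize_edges(raw), genes=list(m.gene_ids))
    return m, ref


def canonicalize_edges(edges: set[tuple[str, str]]) -> set[frozenset]:
    """Drop self-loops; collapse direction (and implicitly sign)."""
    return {frozenset(e[:2]) for e in edges if e[0] != e[1]}


def compute_metrics(
    pred: set[frozenset], ref: set[frozenset], universe: list[str]
) -> BenchmarkResult:
    """Confusion counts and derived metrics over all unordered non-self pairs."""
    genes = set(universe)
    for pair in pred | ref:
        if not set(pair) <= genes:
            raise ValueError(f"edge {set(pair)} contains genes outside the universe")
    n = len(genes)
    total_pairs = n * (n - 1) // 2
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = total_pairs - tp - fp - fn

    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if precision + recall == 0:
        undefined.append("f1")
    return BenchmarkResult(
        precision=precision, recall=recall, specificity=specificity, f1=f1,
        tp=tp, fp=fp, fn=fn, tn=tn, undefined=undefined,
    )


def infer_benchmark_network(
    m: ExpressionMatrix,
    cfg: ADDSTCNConfig | None = None,
    R: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    subsample_frac: float = 0.9,
    max_steps: int | None = None,
    standardize: bool = True,
) -> set[frozenset]:
    """Run the modified pipeline (no co-diff subtraction) on one dataset.

    The matrix is pseudotime-ordered once; each of the R permutation runs
    bootstraps an order-preserving cell subsample and a fresh training seed,
    the background runs additionally shuffle every gene across cells, and
    the negative binomial threshold prunes weakly recurrent edges. Returns
    the canonical (undirected, unsigned, self-loop-free) predicted pairs.

    Each gene series is z-scored before discovery (``standardize``): the
    co-differential series of the paired pipeline are naturally centered,
    and without centering the network spends its learned improvement
    fitting the series mean, drowning every cause's contribution.
    """
    cfg = cfg or ADDSTCNConfig()
    ordering = order_cells(m, seed=seed)
    ordered = apply_ordering(m, ordering)
    n_sub = max(2, int(round(subsample_frac * ordered.n_cells)))

    def _as_series(counts: np.ndarray) -> np.ndarray:
        if not standardize:
            return counts
        sd = counts.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (counts - counts.mean(axis=1, keepdims=True)) / sd

    # detection counts are tallied per canonical (unordered) pair: the
    # scoring protocol disregards direction, sign and self-loops, so the
    # two directions of one interaction must pool their recurrence before
    # the significance threshold is applied
    observed: dict[frozenset, int] = {}
    background: dict[frozenset, int] = {}
    for r in range(R):
        run_seed = seed + r
        sub = subsample_cells(ordered, n_sub, seed=run_seed)
        run_cfg = ADDSTCNConfig(**{**cfg.__dict__, "seed": run_seed})
        X = CoDiffMatrix(X=_as_series(sub.counts), gene_ids=list(sub.gene_ids))
        g = discover(X, cfg=run_cfg, max_steps=max_steps)
        for pair in canonicalize_edges({(e.cause, e.target) for e in g.edges}):
            observed[pair] = observed.get(pair, 0) + 1

        rng = np.random.default_rng([run_seed, 0xBACC])
        shuf = shuffle_within_genes(sub, rng)
        Xb = CoDiffMatrix(X=_as_series(shuf.counts), gene_ids=list(shuf.gene_ids))
        gb = discover(Xb, cfg=run_cfg, max_steps=max_steps)
        for pair in canonicalize_edges({(e.cause, e.target) for e in gb.edges}):
            background[pair] = background.get(pair, 0) + 1

    n = m.n_genes
    model = fit_count_model(list(background.values()), n * (n - 1) // 2, alpha, R)
    return {
        pair for pair, count in observed.items()
        if count >= max(model.min_detections, 1)
    }


def run_benchmark(
    directory: str | os.PathLike,
    cfg: ADDSTCNConfig | None = None,
    R: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    subsample_frac: float = 0.9,
) -> BenchmarkResult:
    """Load one dataset directory, infer, and score against its reference."""
    m, ref = load_beeline(directory)
    pred = infer_benchmark_network(
        m, cfg=cfg, R=R, alpha=alpha, seed=seed, subsample_frac=subsample_frac
    )
    return compute_metrics(pred, ref.edges, list(m.gene_ids))
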