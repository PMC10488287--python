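"""Permutation-based significance testing with a negative binomial null.

The discovery procedure is repeated over random cell subsamples and the
detection count of every (cause, target, sign) identity is tallied. A
background table built from gene-wise shuffled matrices parameterizes a
negative binomial (method of moments, Poisson fallback) from which the
minimum number of detections required for significance is derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .causal import ADDSTCNConfig, discover
from .codiff import CoDiffMatrix, compute_codiff
from .matrix import ExpressionMatrix
from .preprocess import subsample_cells

logger = logging.getLogger(__name__)

EdgeKey = tuple[str, str, str]  # (cause, target, sign)


@dataclass
class EdgeFrequencyTable:
    counts: dict[EdgeKey, int]
    R: int
    genes: list[str]
    is_background: bool = False
    delays: dict[EdgeKey, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, c in self.counts.items():
            if not (0 <= c <= self.R):
                raise ValueError(f"count {c} for {k} outside [0, {self.R}]")

    def add(self, key: EdgeKey, delay: int) -> None:
        self.counts[key] = self.counts.get(key, 0) + 1
        self.delays.setdefault(key, []).append(delay)

    def pair_counts(self) -> dict[tuple[str, str], int]:
        """Per-(cause, target) totals, signs pooled."""
        out: dict[tuple[str, str], int] = {}
        for (c, t, _s), n in self.counts.items():
            out[(c, t)] = out.get((c, t), 0) + n
        return out


@dataclass
class SignificanceModel:
    mean: float
    variance: float
    alpha: float
    min_detections: int
    R: int
    universe_size: int
    distribution: object  # frozen scipy distribution

    def tail(self, count: int) -> float:
        """P(background count >= count)."""
        if self.mean == 0:
            return 0.0 if count > 0 else 1.0
        return float(self.distribution.sf(count - 1))


@dataclass
class SignificantEdge:
    cause: str
    target: str
    sign: str
    delay: int
    count: int
    tail_prob: float


def _one_run(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    targets: list[str],
    cfg: ADDSTCNConfig,
    run_seed: int,
    table: EdgeFrequencyTable,
    max_steps: int | None,
) -> None:
    n = min(case.n_cells, control.n_cells)
    case_r = subsample_cells(case, n, seed=run_seed) if case.n_cells > n else case
    control_r = subsample_cells(control, n, seed=run_seed) if control.n_cells > n else control
    X = compute_codiff(case_r, control_r)
    run_cfg = ADDSTCNConfig(**{**cfg.__dict__, "seed": run_seed})
    graph = discover(X, targets=targets, cfg=run_cfg, max_steps=max_steps)
    for e in graph.edges:
        table.add((e.cause, e.target, e.sign), e.delay)


def run_permutations(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    targets: list[str] | None,
    R: int,
    cfg: ADDSTCNConfig | None = None,
    seed: int = 0,
    max_steps: int | None = None,
) -> EdgeFrequencyTable:
    """Repeat subsample -> co-diff -> discovery R times, tallying detections.

    Both inputs must already be pseudotime-ordered; per-run subsampling of
    the larger condition preserves that order. Run r uses seed ``seed + r``
    for subsampling, network initialization and permutation shuffles.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    cfg = cfg or ADDSTCNConfig()
    if targets is None:
        targets = list(case.gene_ids)
    table = EdgeFrequencyTable(counts={}, R=R, genes=list(case.gene_ids))
    for r in range(R):
        _one_run(case, control, targets, cfg, seed + r, table, max_steps)
    return table


def shuffle_within_genes(m: ExpressionMatrix, rng: np.random.Generator) -> ExpressionMatrix:
    """Independently permute each gene's values across cells.

    Destroys cross-gene and trajectory structure while preserving every
    gene's marginal distribution.
    """
    out = m.copy()
    for g in range(out.n_genes):
        out.counts[g, :] = out.counts[g, rng.permutation(out.n_cells)]
    return out


def background_run(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    targets: list[str] | None,
    R: int,
    cfg: ADDSTCNConfig | None = None,
    seed: int = 0,
    max_steps: int | None = None,
) -> EdgeFrequencyTable:
    """As :func:`run_permutations` but on gene-wise shuffled matrices."""
    if R < 1:
        raise ValueError("R must be >= 1")
    cfg = cfg or ADDSTCNConfig()
    if targets is None:
        targets = list(case.gene_ids)
    table = EdgeFrequencyTable(
        counts={}, R=R, genes=list(case.gene_ids), is_background=True
    )
    for r in range(R):
        rng = np.random.default_rng([seed + r, 0xBACC])
        case_s = shuffle_within_genes(case, rng)
        control_s = shuffle_within_genes(control, rng)
        _one_run(case_s, control_s, targets, cfg, seed + r, table, max_steps)
    return table


def fit_count_model(
    counts: list[int] | np.ndarray, universe: int, alpha: float, R: int
) -> SignificanceModel:
    """Method-of-moments NB fit (Poisson fallback) over a count universe.

    ``counts`` are the nonzero detection counts; the remaining
    ``universe - len(counts)`` entries are zeros. ``min_detections`` is the
    smallest m with P(count >= m) <= alpha, floored at 2 for R >= 2 (a
    single detection is never "consistent recall"; without the floor any
    one-run fluke becomes significant under a sparse background and the
    shuffled-input null is no longer clean) and capped at R.
    """
    if universe == 0:
        raise ValueError("empty candidate-pair universe")
    values = np.zeros(universe)
    observed = list(counts)[:universe]
    values[: len(observed)] = observed
    mean = float(values.mean())
    var = float(values.var(ddof=1)) if universe > 1 else 0.0

    if mean == 0:
        dist = scipy.stats.poisson(0.0)
    elif var > mean:
        n_param = mean**2 / (var - mean)
        p_param = mean / var
        dist = scipy.stats.nbinom(n_param, p_param)
    else:
        dist = scipy.stats.poisson(mean)

    if alpha >= 1:
        m = 0
    else:
        m = 2 if R >= 2 else 1
        while m <= R:
            tail = 0.0 if mean == 0 else float(dist.sf(m - 1))
            if tail <= alpha:
                break
            m += 1
        m = min(m, R)
    return SignificanceModel(
        mean=mean, variance=var, alpha=alpha, min_detections=m,
        R=R, universe_size=universe, distribution=dist,
    )


def fit_significance(background: EdgeFrequencyTable, alpha: float = 0.05) -> SignificanceModel:
    """Fit the background detection-count null and derive min_detections.

    Per-(cause, target) background counts — zeros included over the directed
    non-self pair universe — are fitted by method-of-moments negative
    binomial, falling back to Poisson when the sample variance does not
    exceed the mean. ``min_detections`` is the smallest m with
    P(count >= m) <= alpha (at least 1 for alpha < 1).
    """
    if not background.is_background:
        raise ValueError("fit_significance expects a background table")
    n_genes = len(background.genes)
    universe = n_genes * (n_genes - 1)
    return fit_count_model(
        list(background.pair_counts().values()), universe, alpha, background.R
    )


def significant_edges(
    observed: EdgeFrequencyTable, model: SignificanceModel
) -> list[SignificantEdge]:
    """Call edges whose detection count clears the background threshold.

    Significance is assessed on the per-(cause, target) total count; the
    majority sign across detecting runs is carried (ties dropped and
    logged) along with the modal delay.
    """
    if observed.R != model.R:
        raise ValueError(f"observed R={observed.R} but model fitted for R={model.R}")
    by_pair: dict[tuple[str, str], dict[str, int]] = {}
    for (c, t, s), n in observed.counts.items():
        by_pair.setdefault((c, t), {})[s] = n
    out: list[SignificantEdge] = []
    for (c, t), signs in sorted(by_pair.items()):
        total = sum(signs.values())
        if total < max(model.min_detections, 1):
            continue
        best = max(signs.values())
        winners = sorted(s for s, n in signs.items() if n == best)
        if len(winners) > 1:
            logger.warning("sign tie for edge %s->%s (%s); dropped", c, t, signs)
            continue
        sign = winners[0]
        delays: list[int] = []
        for s in signs:
            delays.extend(observed.delays.get((c, t, s), []))
        vals, cnts = np.unique(delays, return_counts=True)
        modal_delay = int(vals[np.argmax(cnts)]) if len(vals) else 0
        out.append(SignificantEdge(
            cause=c, target=t, sign=sign, delay=modal_delay,
            count=total, tail_prob=model.tail(total),
        ))
    return out


def frequency_histogram(table: EdgeFrequencyTable) -> dict[int, int]:
    """Number of distinct edges detected at each frequency (1..R)."""
    hist: dict[int, int] = {}
    for n in table.pair_counts().values():
        hist[n] = hist.get(n, 0) + 1
    return dict(sorted(hist.items()))
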