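"""Temporal causal discovery over co-differential series.

For each target gene a network is trained to predict its series from the
past of all series; attention scores are gap-thresholded into potential
causes, each potential cause is validated by permutation importance, and
the pseudotime delay is read from the position of the highest first-layer
kernel weight.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from ..codiff import CoDiffMatrix, regulation_sign
from . import autograd as ag
from .network import ADDSTCN, ADDSTCNConfig, receptive_field

logger = logging.getLogger(__name__)


@dataclass
class AttentionScores:
    """Raw attention vector, gap threshold, survivors and their softmax."""

    scores: np.ndarray
    tau: float
    survivors: np.ndarray  # indices with score >= tau
    normalized: np.ndarray  # softmax over survivors, exact zeros elsewhere


@dataclass
class TrainedTCN:
    target: int
    model: ADDSTCN
    first_loss: float
    ground_loss: float
    predictions: np.ndarray
    attention: np.ndarray

    def __post_init__(self) -> None:
        if self.first_loss < 0 or self.ground_loss < 0:
            raise ValueError("losses must be non-negative")


@dataclass
class ValidatedEdge:
    cause: str
    target: str
    delay: int
    sign: str  # "positive" | "negative"
    attention: float
    delta_loss: float


@dataclass
class CausalGraph:
    genes: list[str]
    edges: list[ValidatedEdge] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(e.cause, e.target, e.sign) for e in self.edges}

    def pair_set(self) -> set[tuple[str, str]]:
        return {(e.cause, e.target) for e in self.edges}


def train_target(X: CoDiffMatrix, j: int, cfg: ADDSTCNConfig) -> TrainedTCN:
    """Fit the per-target network with Adam; record first and final MSE."""
    if X.T <= receptive_field(cfg):
        logger.warning(
            "series length %d <= receptive field %d; history is truncated by padding",
            X.T, receptive_field(cfg),
        )
    # seed by gene label, not row index, so row order only relabels results
    tkey = zlib.crc32(X.gene_ids[j].encode())
    rng = np.random.default_rng([cfg.seed, tkey])
    channel_rngs = [
        np.random.default_rng([cfg.seed, tkey, zlib.crc32(g.encode())])
        for g in X.gene_ids
    ]
    model = ADDSTCN(X.n_genes, j, cfg, rng, channel_rngs=channel_rngs)
    opt = ag.Adam(model.params, lr=cfg.learning_rate)
    target_series = X.X[j].reshape(1, -1)
    first_loss = None
    for _ in range(cfg.epochs):
        opt.zero_grad()
        loss = ag.mse(model.forward(X.X), target_series)
        if first_loss is None:
            first_loss = float(loss.data)
        loss.backward()
        opt.step()
    pred = model.forward(X.X).data
    ground_loss = float(np.mean((pred - target_series) ** 2))
    return TrainedTCN(
        target=j,
        model=model,
        first_loss=first_loss,
        ground_loss=ground_loss,
        predictions=pred.ravel(),
        attention=model.attention_scores(),
    )


def threshold_attention(scores: np.ndarray) -> AttentionScores:
    """Split the attention vector at the largest gap of its sorted values.

    Scores are sorted descending; the threshold tau is the score just above
    the largest adjacent gap, scores below tau are truncated to exactly
    zero, and the survivors are renormalized with a softmax. All-equal
    scores keep every entry (no gap). A single-entry vector yields no
    potential causes.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    n = len(scores)
    if n <= 1:
        return AttentionScores(
            scores=scores, tau=np.inf, survivors=np.array([], dtype=int),
            normalized=np.zeros(n),
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    gaps = s[:-1] - s[1:]
    if np.all(gaps == 0):
        survivors = order
        tau = float(s[-1])
    else:
        g = int(np.argmax(gaps))
        tau = float(s[g])
        survivors = order[: g + 1]
    normalized = np.zeros(n)
    kept = scores[survivors]
    e = np.exp(kept - kept.max())
    normalized[survivors] = e / e.sum()
    return AttentionScores(
        scores=scores, tau=tau, survivors=np.sort(survivors), normalized=normalized
    )


def permutation_importance(
    trained: TrainedTCN,
    X: CoDiffMatrix,
    i: int,
    seed: int = 0,
    pi_ratio: float | None = None,
    n_shuffles: int | None = None,
) -> tuple[bool, float]:
    """Validate potential cause i by time-shuffling its series.

    The trained network is re-evaluated with series i permuted in time;
    ``delta_loss = first_epoch_loss - permuted_loss`` is the improvement
    that survives the permutation. The cause is accepted iff
    ``delta_loss <= pi_ratio * L_G``: permuting a true cause must destroy
    most of the learned fit, keeping the surviving improvement small. The
    reference ``L_G`` is the final training loss by default
    (``pi_reference='final'``) or the learned improvement
    ``first_loss - final_loss`` (``'improvement'``).

    With ``pi_shuffles > 1`` the deltas are either averaged before applying
    the rule (``pi_aggregate='mean'``) or the rule must hold for every
    shuffle (``'all'``, conservative). A single shuffle is the default.
    """
    cfg = trained.model.cfg
    ratio = cfg.pi_ratio if pi_ratio is None else pi_ratio
    shuffles = cfg.pi_shuffles if n_shuffles is None else n_shuffles
    rng = np.random.default_rng([
        seed,
        zlib.crc32(X.gene_ids[trained.target].encode()),
        zlib.crc32(X.gene_ids[i].encode()),
    ])
    target_series = X.X[trained.target]
    deltas = []
    for _ in range(shuffles):
        Xp = X.X.copy()
        Xp[i] = Xp[i][rng.permutation(X.T)]
        deltas.append(trained.first_loss - trained.model.evaluate(Xp, target_series))
    if cfg.pi_reference == "improvement":
        threshold = ratio * (trained.first_loss - trained.ground_loss)
    else:
        threshold = ratio * trained.ground_loss
    if cfg.pi_aggregate == "all":
        delta_loss = float(np.max(deltas))
        accepted = all(d <= threshold for d in deltas)
    else:
        delta_loss = float(np.mean(deltas))
        accepted = delta_loss <= threshold
    return accepted, delta_loss


def pi_decision(first_loss: float, permuted_loss: float, ground_loss: float,
                pi_ratio: float = 0.8) -> bool:
    """The bare acceptance rule: first_loss - permuted_loss <= ratio * ground."""
    return (first_loss - permuted_loss) <= pi_ratio * ground_loss


def estimate_delay(trained: TrainedTCN, i: int) -> int:
    """Pseudotime-step delay from the argmax of the first-layer kernel.

    The dilation-1 layer's taps map one-to-one onto input lags: the
    most-recent tap is delay 0 for an exogenous channel and delay 1 for the
    (pre-shifted) autoregressive channel. "Highest" is read as largest
    magnitude — downstream sign flips make the raw sign of a tap
    uninformative. Ties resolve to the smallest delay.
    """
    w = np.abs(trained.model.first_layer_kernel(i))
    K = len(w)
    # last occurrence of the max -> most recent tap -> smallest delay
    k = K - 1 - int(np.argmax(w[::-1]))
    base = K - 1 - k
    return base + 1 if i == trained.target else base


def discover(
    X: CoDiffMatrix,
    targets: list[str] | None = None,
    cfg: ADDSTCNConfig | None = None,
    max_steps: int | None = None,
    self_loops: bool = False,
) -> CausalGraph:
    """Run the full per-target procedure and assemble the causal graph.

    For each target: train, gap-threshold the attention scores, validate
    each potential cause by permutation importance, estimate its delay, and
    classify the regulation sign from the correlation of the two series.
    Edges with delay exceeding ``max_steps`` (when set) are dropped.
    """
    cfg = cfg or ADDSTCNConfig()
    if targets is None:
        targets = list(X.gene_ids)
    graph = CausalGraph(genes=list(X.gene_ids))
    for tg in targets:
        j = X.gene_index(tg)
        trained = train_target(X, j, cfg)
        att = threshold_attention(trained.attention)
        for i in att.survivors:
            i = int(i)
            if i == j and not self_loops:
                continue
            ok, dl = permutation_importance(trained, X, i, seed=cfg.seed)
            if not ok:
                continue
            delay = estimate_delay(trained, i)
            if max_steps is not None and delay > max_steps:
                continue
            try:
                sign = regulation_sign(X.X[i], X.X[j])
            except ValueError:
                logger.info("zero-variance series for %s->%s; defaulting sign to positive",
                            X.gene_ids[i], tg)
                sign = "positive"
            graph.edges.append(ValidatedEdge(
                cause=X.gene_ids[i], target=tg, delay=delay, sign=sign,
                attention=float(trained.attention[i]), delta_loss=float(dl),
            ))
    return graph
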