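"""Synthetic fixtures with known ground truth.

Three generators cover every stage of the pipeline without any downloads:

* :func:`generate_lagged_system` — vector-autoregressive-style series with
  planted lagged, signed dependencies; the causal core's end-to-end oracle.
* :func:`generate_case_control` — paired negative-binomial count matrices
  with trajectory structure, planted case-vs-control responder modules, and
  decoy pairs that co-vary within conditions but have no co-differential
  relationship.
* :func:`generate_trajectory_dataset` — a single benchmark-style expression
  matrix (plus its reference network) in which a signed, lagged cascade
  propagates along a latent trajectory.

:func:`inject_dropout` adds artificial zeros matrix-wide up to a target
total zero fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codiff import CoDiffMatrix
from .matrix import ExpressionMatrix

SignedEdge = tuple[str, str, str]  # (cause, target, "+"/"-")


@dataclass
class PlantedSystem:
    """Specification of a lagged linear system with known truth edges."""

    n_genes: int = 10
    T: int = 200
    edges: list[tuple[int, int, int, int, float]] = field(default_factory=list)
    # (cause index, target index, lag >= 0, sign +-1, effect size)
    noise_sd: float = 0.3
    driver_smoothness: float = 0.6  # AR(1) coefficient of parentless genes
    seed: int = 0

    def __post_init__(self) -> None:
        for i, j, lag, sign, eff in self.edges:
            if lag < 0:
                raise ValueError("lags must be >= 0")
            if lag >= self.T:
                raise ValueError(f"lag {lag} >= series length {self.T}")
            if sign not in (-1, 1):
                raise ValueError("sign must be +-1")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
            if lag == 0 and i == j:
                raise ValueError("zero-lag self edge is not allowed")


def generate_lagged_system(spec: PlantedSystem) -> tuple[CoDiffMatrix, set[tuple[int, int]]]:
    """Simulate the planted system; returns the series and the truth edges.

    Target series follow ``x_j[t] = sum sign * effect * x_i[t - lag] + eps``;
    genes without parents are mutually independent unit-variance AR(1)
    series (coefficient ``driver_smoothness``; 0 gives white noise). Mild
    temporal smoothness keeps the contemporaneous cause/target correlation
    informative for the regulation sign.
    """
    rng = np.random.default_rng(spec.seed)
    N, T = spec.n_genes, spec.T
    phi = spec.driver_smoothness
    X = rng.standard_normal((N, T))
    if phi:
        for t in range(1, T):
            X[:, t] = phi * X[:, t - 1] + np.sqrt(1 - phi**2) * X[:, t]
    targets = {j for _, j, *_ in spec.edges}
    for j in targets:
        X[j] = rng.standard_normal(T) * spec.noise_sd
    # lag-respecting sequential fill (supports chains and cycles with lag >= 1)
    for t in range(T):
        for i, j, lag, sign, eff in spec.edges:
            if t - lag >= 0:
                X[j, t] += sign * eff * X[i, t - lag]
    truth = {(i, j) for i, j, *_ in spec.edges}
    return CoDiffMatrix(X=X, gene_ids=[f"g{k}" for k in range(N)]), truth


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson sampling; variance = m + dispersion * m^2."""
    mean = np.maximum(mean, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(float)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_case_control(
    n_genes: int = 40,
    n_cells: int = 120,
    goi: str = "GOI",
    responders: list[tuple[str, int, int]] | None = None,
    n_decoy_pairs: int = 2,
    nb_dispersion: float = 0.2,
    diff_amplitude: float = 0.4,
    coupling_sd: float = 1.0,
    base_scale: float = 50.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Paired NB count matrices along a latent trajectory with planted truth.

    Parameters
    ----------
    responders
        ``(gene_id, lag, sign)`` triples: in the case condition each
        responder tracks the goi both at the mean level (a differential
        bump shifted by ``lag`` trajectory steps) and at the per-cell level
        (a case-only fluctuation factor shared between the goi and its
        responders within every case cell, sign-flipped for repression).
        The within-cell coupling is what makes the dependence causally
        detectable — it cannot be predicted from the responder's own past,
        only from the goi channel — and it survives pseudotime ordering
        errors because it never leaves the cell. Default: three responders
        at lags 1..3.
    n_decoy_pairs
        Pairs of genes sharing a base profile (high within-condition
        correlation) but identical between conditions, so their
        co-differential series are pure noise.

    Returns (case, control, truth) where ``truth`` holds the planted edges,
    decoy gene pairs and latent cell positions for each condition.
    """
    if responders is None:
        responders = [("RESP1", 1, 1), ("RESP2", 2, 1), ("RESP3", 3, -1)]
    rng = np.random.default_rng(seed)

    genes = [goi] + [g for g, _, _ in responders]
    decoys = []
    for d in range(n_decoy_pairs):
        a, b = f"DECOY{d}A", f"DECOY{d}B"
        decoys.append((a, b))
        genes += [a, b]
    k = 0
    while len(genes) < n_genes:
        genes.append(f"BG{k}")
        k += 1

    # one cell per grid position in each condition -> clean pseudotime truth
    grid = np.linspace(0, 1, n_cells)
    step = 1.0 / n_cells

    centers = rng.uniform(0.2, 0.8, size=len(genes))
    widths = rng.uniform(0.08, 0.25, size=len(genes))
    amps = rng.uniform(1.5, 2.5, size=len(genes))
    base = {
        g: amps[i] * _sigmoid((grid - centers[i]) / widths[i])
        for i, g in enumerate(genes)
    }
    decoy_genes = {g for pair in decoys for g in pair}
    for a, b in decoys:  # shared ramp -> strong within-condition correlation
        base[a] = 3.0 * _sigmoid((grid - centers[genes.index(a)]) / 0.2)
        base[b] = base[a].copy()
    module_genes = {goi} | {g for g, _, _ in responders}
    for g in module_genes:
        # flat baseline: the case-condition bump is the only structure, and
        # repressive (negative) responders have headroom to dip
        base[g] = np.full(n_cells, 1.0)

    def bump(shift_steps: int) -> np.ndarray:
        s0 = 0.5 + shift_steps * step
        return diff_amplitude * np.exp(-(((grid - s0) / 0.15) ** 2))

    diff = {g: np.zeros(n_cells) for g in genes}
    couple_sign = {g: 0 for g in genes}  # 0 = not in the module
    diff[goi] = bump(0)
    couple_sign[goi] = 1
    truth_edges = []
    for g, lag, sign in responders:
        diff[g] = sign * bump(lag)
        couple_sign[g] = sign
        truth_edges.append((goi, g, lag, "+" if sign > 0 else "-"))

    def sample(condition: str, cond_seed: int) -> ExpressionMatrix:
        crng = np.random.default_rng([seed, cond_seed])
        perm = crng.permutation(n_cells)  # cells arrive in random order
        # case-only per-cell factor carried cleanly by the goi; responders
        # receive it attenuated plus their own noise, so the goi channel is
        # the uniquely best predictor of every responder
        fluct = crng.normal(0.0, coupling_sd, size=n_cells)
        rho = 0.75
        mat = np.zeros((len(genes), n_cells))
        for i, g in enumerate(genes):
            mean = base_scale * np.exp(base[g]) / np.exp(base[g]).max()
            if condition == "case":
                mean = mean * np.exp(diff[g])  # bump rides on the baseline
            mu = mean[perm]
            if condition == "case" and couple_sign[g]:
                if g == goi:
                    factor = fluct
                else:
                    own = crng.normal(0.0, coupling_sd, size=n_cells)
                    factor = rho * fluct + np.sqrt(1 - rho**2) * own
                mu = mu * np.exp(couple_sign[g] * factor)
            if g in decoy_genes:
                # decoys: abundant, near-Poisson, so the shared trajectory
                # profile dominates and within-condition correlation is high
                # while the case-minus-control series stays independent noise
                mat[i] = _nb_counts(8.0 * mu, 0.01, crng)
            else:
                mat[i] = _nb_counts(mu, nb_dispersion, crng)
        return ExpressionMatrix(
            counts=mat,
            gene_ids=list(genes),
            cell_ids=[f"{condition}_c{i}" for i in range(n_cells)],
            condition=condition,
        ), perm

    case, case_perm = sample("case", 1)
    control, control_perm = sample("control", 2)
    truth = {
        "goi": goi,
        "responders": truth_edges,
        "decoys": decoys,
        "latent_case": grid[case_perm],
        "latent_control": grid[control_perm],
    }
    return case, control, truth


def inject_dropout(
    m: ExpressionMatrix, target_total_zero_fraction: float, seed: int = 0
) -> ExpressionMatrix:
    """Zero uniformly sampled nonzero entries until the matrix-wide zero
    fraction reaches the target (within one entry). Existing entries are
    otherwise untouched."""
    size = m.counts.size
    current = float((m.counts == 0).sum()) / size
    if target_total_zero_fraction < current - 1e-12:
        raise ValueError(
            f"target zero fraction {target_total_zero_fraction:.4f} below current "
            f"{current:.4f}; dropout can only be added"
        )
    n_new = int(round(target_total_zero_fraction * size)) - int((m.counts == 0).sum())
    out = m.copy()
    if n_new <= 0:
        return out
    rng = np.random.default_rng(seed)
    nz = np.flatnonzero(out.counts.ravel() != 0)
    pick = rng.choice(nz, size=min(n_new, len(nz)), replace=False)
    flat = out.counts.ravel()
    flat[pick] = 0.0
    out.counts = flat.reshape(m.counts.shape)
    out.log = m.log + [
        f"inject_dropout: zero fraction {current:.4f} -> "
        f"{float((out.counts == 0).sum()) / size:.4f} (seed={seed})"
    ]
    return out


# ---------------------------------------------------------------------------
# benchmark-style trajectory datasets with signed, lagged reference cascades
# ---------------------------------------------------------------------------

#: Small signed reference topologies for offline benchmarking: a 7-gene
#: linear cascade, a 6-gene cycle, an 11-gene hematopoietic Boolean-model
#: wiring, and a 5-gene cortical-patterning wiring.
BENCHMARK_TOPOLOGIES: dict[str, list[SignedEdge]] = {
    "LI": [
        ("g1", "g2", "+"), ("g2", "g3", "+"), ("g3", "g4", "+"),
        ("g4", "g5", "+"), ("g5", "g6", "+"), ("g6", "g7", "+"),
        ("g5", "g1", "-"),
    ],
    "CY": [
        ("g1", "g2", "+"), ("g2", "g3", "+"), ("g3", "g4", "+"),
        ("g4", "g5", "+"), ("g5", "g6", "+"), ("g6", "g1", "-"),
    ],
    "HSC": [
        ("Gata2", "Gata1", "+"), ("Gata1", "Gata2", "-"), ("Fog1", "Gata2", "-"),
        ("Pu1", "Gata2", "-"), ("Fli1", "Gata1", "+"), ("Pu1", "Gata1", "-"),
        ("Gata1", "Fog1", "+"), ("Gata1", "EKLF", "+"), ("Fli1", "EKLF", "-"),
        ("Gata1", "Fli1", "+"), ("EKLF", "Fli1", "-"), ("Gata1", "SCL", "+"),
        ("Pu1", "SCL", "-"), ("Gata1", "Cebpa", "-"), ("Fog1", "Cebpa", "-"),
        ("SCL", "Cebpa", "-"), ("Cebpa", "Pu1", "+"), ("Gata1", "Pu1", "-"),
        ("Gata2", "Pu1", "-"), ("Pu1", "cJun", "+"), ("Gfi1", "cJun", "-"),
        ("Pu1", "EgrNab", "+"), ("cJun", "EgrNab", "+"), ("Gfi1", "EgrNab", "-"),
        ("Cebpa", "Gfi1", "+"), ("EgrNab", "Gfi1", "-"), ("Pu1", "Gfi1", "+"),
    ],
    "MCAD": [
        ("Fgf8", "Emx2", "-"), ("Emx2", "Fgf8", "-"), ("Fgf8", "Sp8", "+"),
        ("Sp8", "Fgf8", "+"), ("Emx2", "Pax6", "-"), ("Pax6", "Emx2", "-"),
        ("Sp8", "Emx2", "-"), ("Fgf8", "Coup", "-"), ("Coup", "Fgf8", "-"),
        ("Fgf8", "Pax6", "+"), ("Emx2", "Coup", "+"), ("Coup", "Pax6", "-"),
        ("Coup", "Sp8", "-"),
    ],
}


def generate_trajectory_dataset(
    edges: list[SignedEdge],
    genes: list[str] | None = None,
    n_cells: int = 200,
    lag: int = 3,
    noise_sd: float = 0.05,
    process_noise_sd: float = 0.4,
    process_noise_phi: float = 0.0,
    baseline_amplitude: float = 0.5,
    seed: int = 0,
    shuffle_cells: bool = True,
) -> tuple[ExpressionMatrix, set[frozenset], np.ndarray]:
    """Expression along a latent trajectory driven by a signed cascade.

    Every gene carries a smooth staggered sigmoid baseline (the ramps
    jointly make the cell ordering recoverable) plus per-cell stochastic
    fluctuations that propagate through the reference edges within each
    cell: a cell whose cause gene fluctuates up sees its activated targets
    fluctuate up (and repressed targets down) in the same cell, the way
    stochastic simulations of a regulatory circuit couple genes sampled at
    one snapshot. A gene's own innovation reaches its targets only through
    the direct edges, so a direct cause is indispensable for predicting its
    target while indirect ancestors remain redundant given the intermediate
    — the structure the permutation-importance validation detects. ``lag``
    additionally delays the propagation along the trajectory grid.

    Returns the matrix (cells in random order unless ``shuffle_cells=False``),
    the canonical reference pairs, and the latent position of every cell.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        seen: list[str] = []
        for a, b, _ in edges:
            for g in (a, b):
                if g not in seen:
                    seen.append(g)
        genes = seen
    idx = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    T = n_cells

    parents: dict[int, list[tuple[int, str]]] = {i: [] for i in range(N)}
    for a, b, s in edges:
        parents[idx[b]].append((idx[a], s))

    t = np.arange(T)
    phi, psd = process_noise_phi, process_noise_sd

    # staggered monotone baselines spanning the trajectory
    centers = np.linspace(0.15, 0.85, N)[np.argsort(rng.permutation(N))]
    baseline = np.array([
        baseline_amplitude * _sigmoid((t - centers[i] * T) / (0.1 * T))
        for i in range(N)
    ])

    # per-gene innovations, slightly smoothed along the trajectory
    own = np.empty((N, T))
    for i in range(N):
        w = rng.standard_normal(T)
        for s in range(1, T):
            w[s] = phi * w[s - 1] + np.sqrt(1 - phi**2) * w[s]
        own[i] = psd * w

    # propagate fluctuations through the cascade; lag 0 couples genes within
    # a cell (solved as a linear fixed point, attenuation keeps cycles
    # contractive), lag >= 1 delays along the trajectory grid
    gain = 0.9
    if lag == 0:
        W = np.zeros((N, N))
        for j in range(N):
            for i, s in parents[j]:
                W[j, i] = (gain / len(parents[j])) * (1.0 if s == "+" else -1.0)
        dev = np.linalg.solve(np.eye(N) - W, own)
    else:
        dev = own.copy()
        for step in range(T):
            for j in range(N):
                if not parents[j]:
                    continue
                acc = 0.0
                for i, s in parents[j]:
                    past = dev[i, step - lag] if step - lag >= 0 else 0.0
                    acc += past if s == "+" else -past
                dev[j, step] = own[j, step] + gain * acc / len(parents[j])
    # offset keeps censoring at zero rare so the couplings stay observable
    prof = np.clip(baseline + dev + 1.5, 0.0, None)

    order = rng.permutation(T) if shuffle_cells else np.arange(T)
    counts = np.clip(prof[:, order] + rng.normal(0, noise_sd, size=(N, T)), 0.0, None)
    m = ExpressionMatrix(
        counts=counts,
        gene_ids=list(genes),
        cell_ids=[f"cell{i}" for i in range(T)],
    )
    ref = {frozenset((a, b)) for a, b, _ in edges if a != b}
    return m, ref, t[order] / T


def write_benchmark_surrogate(
    name: str, directory, n_cells: int = 200, seed: int = 0
) -> None:
    """Materialize a BEELINE-style dataset directory for a bundled topology."""
    import os

    import pandas as pd

    edges = BENCHMARK_TOPOLOGIES[name.upper()]
    m, _, _ = generate_trajectory_dataset(edges, n_cells=n_cells, seed=seed)
    os.makedirs(directory, exist_ok=True)
    m.to_csv(os.path.join(directory, "ExpressionData.csv"))
    pd.DataFrame(
        [{"Gene1": a, "Gene2": b, "Type": s} for a, b, s in edges]
    ).to_csv(os.path.join(directory, "refNetwork.csv"), index=False)
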