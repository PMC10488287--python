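"""End-to-end orchestration: ingest -> QC -> order -> co-diff -> discovery
-> significance -> serialized networks, plus the dropout-robustness and
condition-flip protocols."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .causal import ADDSTCNConfig
from .codiff import compute_codiff, filter_genes_by_dropout, select_candidates
from .grn_io import AnnotatedGRN, merge_grns, write_cytoscape_table, write_graphml
from .matrix import ExpressionMatrix, load_matrix
from .preprocess import QCConfig, normalize, qc_filter, subsample_cells
from .pseudotime import apply_ordering, order_cells
from .significance import (
    background_run,
    fit_significance,
    frequency_histogram,
    run_permutations,
    significant_edges,
)
from .synth import inject_dropout

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """User-facing parameters of one pipeline invocation."""

    case_path: str | None = None
    control_path: str | None = None
    genes_of_interest: list[str] = field(default_factory=list)
    permutations: int = 100
    top_k: int = 100
    max_dropout: float = 0.9
    alpha: float = 0.05
    max_steps: int | None = None
    seed: int = 0
    output_dir: str | None = None
    apply_qc: bool = True
    qc: QCConfig = field(default_factory=QCConfig)
    tcn: ADDSTCNConfig = field(default_factory=ADDSTCNConfig)
    target_sum: float = 1e4

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@dataclass
class GoiResult:
    goi: str
    grn: AnnotatedGRN
    candidates: list[tuple[str, float]]
    observed_histogram: dict[int, int]
    background_histogram: dict[int, int]
    min_detections: int


@dataclass
class PipelineResult:
    per_goi: dict[str, GoiResult]
    merged: AnnotatedGRN
    output_dir: str | None


def prepare_conditions(
    cfg: RunConfig,
    case: ExpressionMatrix | None = None,
    control: ExpressionMatrix | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Load, QC, dropout-filter, normalize and pseudotime-order both inputs."""
    if case is None:
        case = _stage("load")(load_matrix)(cfg.case_path, condition="case")
    if control is None:
        control = _stage("load")(load_matrix)(cfg.control_path, condition="control")
    for goi in cfg.genes_of_interest:
        if goi not in case.gene_ids or goi not in control.gene_ids:
            raise StageError(f"stage 'ingest' failed: gene of interest {goi!r} not in input data")
    if cfg.apply_qc:
        case = _stage("qc")(qc_filter)(case, cfg.qc)
        control = _stage("qc")(qc_filter)(control, cfg.qc)
    case, control = _stage("dropout_filter")(filter_genes_by_dropout)(
        case, control, cfg.max_dropout, genes_of_interest=cfg.genes_of_interest
    )
    case = _stage("normalize")(normalize)(case, cfg.target_sum)
    control = _stage("normalize")(normalize)(control, cfg.target_sum)
    case_ord = _stage("pseudotime")(order_cells)(case, seed=cfg.seed)
    control_ord = _stage("pseudotime")(order_cells)(control, seed=cfg.seed + 1)
    case_o = apply_ordering(case, case_ord)
    control_o = apply_ordering(control, control_ord)
    return case_o, _align_orientation(case_o, control_o)


def _align_orientation(case_o: ExpressionMatrix, control_o: ExpressionMatrix) -> ExpressionMatrix:
    """Disambiguate the arbitrary direction of the control trajectory.

    Diffusion pseudotime fixes an ordering only up to reflection; pairing a
    forward-ordered case with a backward-ordered control misaligns every
    position-wise difference. The control keeps the orientation whose
    per-gene profiles agree better with the case (summed correlation of
    position-interpolated profiles, forward vs reversed).
    """
    n = min(case_o.n_cells, control_o.n_cells)
    grid = np.linspace(0, 1, n)

    def profiles(m: ExpressionMatrix) -> np.ndarray:
        pos = np.linspace(0, 1, m.n_cells)
        return np.vstack([np.interp(grid, pos, row) for row in m.counts])

    pc, pn = profiles(case_o), profiles(control_o)

    def score(b: np.ndarray) -> float:
        total = 0.0
        for x, y in zip(pc, b):
            if x.std() > 0 and y.std() > 0:
                total += float(np.corrcoef(x, y)[0, 1])
        return total

    if score(pn[:, ::-1]) > score(pn):
        logger.info("control trajectory reversed to match case orientation")
        return control_o.subset_cells(np.arange(control_o.n_cells)[::-1])
    return control_o


def run_full(
    cfg: RunConfig,
    case: ExpressionMatrix | None = None,
    control: ExpressionMatrix | None = None,
) -> PipelineResult:
    """Execute the whole pipeline for every gene of interest.

    Matrices may be passed directly (already-loaded raw counts) instead of
    reading ``cfg.case_path``/``cfg.control_path``. All randomness derives
    from ``cfg.seed``; rerunning with the same config reproduces every
    output byte for byte.
    """
    if not cfg.genes_of_interest:
        raise StageError("stage 'config' failed: no genes of interest given")
    case_o, control_o = prepare_conditions(cfg, case, control)

    per_goi: dict[str, GoiResult] = {}
    for goi in cfg.genes_of_interest:
        n = min(case_o.n_cells, control_o.n_cells)
        screen_case = subsample_cells(case_o, n, seed=cfg.seed) if case_o.n_cells > n else case_o
        screen_control = (
            subsample_cells(control_o, n, seed=cfg.seed) if control_o.n_cells > n else control_o
        )
        X_screen = _stage("codiff")(compute_codiff)(screen_case, screen_control)
        cand = _stage("candidates")(select_candidates)(X_screen, goi, cfg.top_k)
        genes = [goi] + cand.genes
        case_g = case_o.subset_genes(genes)
        control_g = control_o.subset_genes(genes)

        observed = _stage("permutations")(run_permutations)(
            case_g, control_g, None, cfg.permutations, cfg.tcn,
            seed=cfg.seed, max_steps=cfg.max_steps,
        )
        background = _stage("background")(background_run)(
            case_g, control_g, None, cfg.permutations, cfg.tcn,
            seed=cfg.seed + 10_000, max_steps=cfg.max_steps,
        )
        model = _stage("significance")(fit_significance)(background, cfg.alpha)
        edges = significant_edges(observed, model)
        grn = AnnotatedGRN.from_significant(edges, goi, genes=[goi])
        per_goi[goi] = GoiResult(
            goi=goi,
            grn=grn,
            candidates=cand.candidates,
            observed_histogram=frequency_histogram(observed),
            background_histogram=frequency_histogram(background),
            min_detections=model.min_detections,
        )

    merged = merge_grns([r.grn for r in per_goi.values()])
    result = PipelineResult(per_goi=per_goi, merged=merged, output_dir=cfg.output_dir)
    if cfg.output_dir:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: RunConfig, result: PipelineResult) -> None:
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "run_config.json"), "w") as fh:
        fh.write(cfg.to_json())
    for goi, r in result.per_goi.items():
        write_graphml(r.grn, os.path.join(out, f"grn_{goi}.graphml"))
        _write_edges_tsv(r.grn, os.path.join(out, f"edges_{goi}.tsv"))
        _write_histogram(r, os.path.join(out, f"histogram_{goi}"))
    write_graphml(result.merged, os.path.join(out, "grn_merged.graphml"))
    write_cytoscape_table(result.merged, os.path.join(out, "cytoscape_edges.tsv"))
    logger.info("outputs written to %s", out)


def _write_edges_tsv(grn: AnnotatedGRN, path: str) -> None:
    import pandas as pd

    rows = [
        {
            "cause": e.cause, "target": e.target, "sign": e.sign,
            "delay": e.delay, "frequency": e.frequency, "p_tail": e.p_tail,
        }
        for e in sorted(grn.edges, key=lambda e: (e.cause, e.target, e.sign))
    ]
    pd.DataFrame(rows, columns=["cause", "target", "sign", "delay", "frequency", "p_tail"]).to_csv(
        path, sep="\t", index=False
    )


def _write_histogram(r: GoiResult, stem: str) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "frequency": list(r.observed_histogram.keys()),
            "n_edges": list(r.observed_histogram.values()),
        }
    )
    df.to_csv(stem + ".tsv", sep="\t", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(df["frequency"], df["n_edges"], color="#4477aa", label="observed")
        if r.background_histogram:
            ax.bar(
                list(r.background_histogram.keys()),
                list(r.background_histogram.values()),
                color="#cc6677", alpha=0.6, label="background",
            )
        ax.axvline(r.min_detections - 0.5, color="k", ls="--", lw=1, label="threshold")
        ax.set_xlabel("detection frequency")
        ax.set_ylabel("edges")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(stem + ".png", dpi=120)
        plt.close(fig)
    except Exception:  # plotting is best-effort; the TSV is the record
        logger.warning("histogram plot failed for %s", r.goi)


def edge_keys_for_goi(result: PipelineResult, goi: str) -> set[tuple[str, str, str]]:
    return result.per_goi[goi].grn.edge_keys()


def overlap_percent(edges: set, baseline: set) -> float:
    """|edges ∩ baseline| / |baseline| * 100 (100.0 for an empty baseline)."""
    if not baseline:
        return 100.0
    return 100.0 * len(edges & baseline) / len(baseline)


def run_robustness(
    cfg: RunConfig,
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    dropout_levels: list[float],
    n_runs: int = 10,
) -> dict:
    """Dropout-injection robustness: per-level edge-set overlap vs baseline.

    For each level d (a fraction of additional artificial zeros), both raw
    matrices are pushed to ``baseline_zero_fraction + d`` total zeros with a
    fresh seed per run, the full pipeline reruns, and the per-run overlap
    percentage against the zero-injection baseline network is recorded.
    """
    goi = cfg.genes_of_interest[0]
    baseline = run_full(cfg, case.copy(), control.copy())
    base_keys = edge_keys_for_goi(baseline, goi)
    z_case = float((case.counts == 0).sum()) / case.counts.size
    z_control = float((control.counts == 0).sum()) / control.counts.size

    report: dict = {"baseline_edges": len(base_keys), "levels": {}}
    for level in dropout_levels:
        overlaps = []
        for run in range(n_runs):
            run_seed = cfg.seed + 1000 * (1 + len(report["levels"])) + run
            if level > 0:
                case_d = inject_dropout(case, min(z_case + level, 1.0), seed=run_seed)
                control_d = inject_dropout(control, min(z_control + level, 1.0), seed=run_seed + 1)
            else:
                case_d, control_d = case.copy(), control.copy()
            run_cfg = dataclasses.replace(cfg, seed=cfg.seed + run, output_dir=None)
            res = run_full(run_cfg, case_d, control_d)
            overlaps.append(overlap_percent(edge_keys_for_goi(res, goi), base_keys))
        report["levels"][level] = {
            "overlaps": overlaps,
            "median": float(np.median(overlaps)),
            "min": float(np.min(overlaps)),
        }
    return report


def run_flip_check(
    cfg: RunConfig, case: ExpressionMatrix, control: ExpressionMatrix
) -> dict:
    """Rerun with case and control swapped; report edge-set agreement."""
    goi = cfg.genes_of_interest[0]
    fwd = edge_keys_for_goi(run_full(cfg, case.copy(), control.copy()), goi)
    rev = edge_keys_for_goi(run_full(cfg, control.copy(), case.copy()), goi)
    union = fwd | rev
    return {
        "forward_edges": len(fwd),
        "flipped_edges": len(rev),
        "jaccard": (len(fwd & rev) / len(union)) if union else 1.0,
        "identical": fwd == rev,
    }
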