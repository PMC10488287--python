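"""Assemble, merge, and serialize annotated regulatory networks."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

from .significance import SignificantEdge


@dataclass(frozen=True)
class GRNEdge:
    cause: str
    target: str
    sign: str
    delay: int
    frequency: int
    p_tail: float
    sources: tuple[str, ...] = ()  # genes of interest that produced this edge


@dataclass
class AnnotatedGRN:
    """A directed signed network with per-edge detection annotations."""

    nodes: list[str] = field(default_factory=list)
    edges: list[GRNEdge] = field(default_factory=list)
    gois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.cause not in node_set or e.target not in node_set:
                raise ValueError(f"edge {e.cause}->{e.target} endpoint not in nodes")

    @classmethod
    def from_significant(
        cls, edges: list[SignificantEdge], goi: str, genes: list[str] | None = None
    ) -> "AnnotatedGRN":
        nodes = set(genes or [])
        nodes.add(goi)
        for e in edges:
            nodes.update((e.cause, e.target))
        return cls(
            nodes=sorted(nodes),
            edges=[
                GRNEdge(e.cause, e.target, e.sign, e.delay, e.count, e.tail_prob, (goi,))
                for e in edges
            ],
            gois=[goi],
        )

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {(e.cause, e.target, e.sign) for e in self.edges}


def _canonical_edges(grn: AnnotatedGRN) -> list[GRNEdge]:
    return sorted(grn.edges, key=lambda e: (e.cause, e.target, e.sign))


def to_networkx(grn: AnnotatedGRN) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for n in sorted(grn.nodes):
        g.add_node(n, is_goi=bool(n in grn.gois))
    for e in _canonical_edges(grn):
        g.add_edge(
            e.cause, e.target, key=e.sign,
            sign=e.sign, delay=int(e.delay), frequency=int(e.frequency),
            p_tail=float(e.p_tail), sources=",".join(e.sources),
        )
    return g


def write_graphml(grn: AnnotatedGRN, path: str | os.PathLike) -> None:
    """Standards-conformant GraphML with typed node/edge attributes.

    Nodes carry ``is_goi``; edges carry ``sign``, ``delay``, ``frequency``,
    ``p_tail`` and a comma-joined ``sources`` list. Output is byte-stable
    for a given graph because nodes and edges are canonically ordered.
    """
    nx.write_graphml(to_networkx(grn), os.fspath(path), encoding="utf-8")


def read_graphml(path: str | os.PathLike) -> AnnotatedGRN:
    g = nx.read_graphml(os.fspath(path), force_multigraph=True)
    nodes = sorted(g.nodes)
    gois = sorted(n for n, d in g.nodes(data=True) if d.get("is_goi"))
    edges = [
        GRNEdge(
            cause=u, target=v, sign=d["sign"], delay=int(d["delay"]),
            frequency=int(d["frequency"]), p_tail=float(d["p_tail"]),
            sources=tuple(s for s in str(d.get("sources", "")).split(",") if s),
        )
        for u, v, d in g.edges(data=True)
    ]
    return AnnotatedGRN(nodes=nodes, edges=sorted(edges, key=lambda e: (e.cause, e.target, e.sign)), gois=gois)


def write_cytoscape_table(grn: AnnotatedGRN, path: str | os.PathLike) -> None:
    """TSV edge table loadable in Cytoscape: source, target, interaction, ..."""
    rows = [
        {
            "source": e.cause,
            "target": e.target,
            "interaction": "activates" if e.sign == "positive" else "represses",
            "delay": e.delay,
            "frequency": e.frequency,
        }
        for e in _canonical_edges(grn)
    ]
    pd.DataFrame(rows, columns=["source", "target", "interaction", "delay", "frequency"]).to_csv(
        os.fspath(path), sep="\t", index=False
    )


def merge_grns(grns: list[AnnotatedGRN]) -> AnnotatedGRN:
    """Node/edge union across per-goi networks.

    Duplicate (cause, target, sign) identities collapse into one edge with
    concatenated source-goi lists and the maximum frequency (its annotations
    follow the highest-frequency contributor). Sign conflicts stay distinct
    edges — signed identity preserves per-goi evidence.
    """
    nodes: set[str] = set()
    gois: list[str] = []
    best: dict[tuple[str, str, str], GRNEdge] = {}
    sources: dict[tuple[str, str, str], list[str]] = {}
    for grn in grns:
        nodes.update(grn.nodes)
        for goi in grn.gois:
            if goi not in gois:
                gois.append(goi)
        for e in grn.edges:
            key = (e.cause, e.target, e.sign)
            srcs = sources.setdefault(key, [])
            for s in e.sources:
                if s not in srcs:
                    srcs.append(s)
            if key not in best or e.frequency > best[key].frequency:
                best[key] = e
    edges = [
        replace(best[key], sources=tuple(sorted(sources[key])))
        for key in sorted(best)
    ]
    return AnnotatedGRN(nodes=sorted(nodes), edges=edges, gois=gois)
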