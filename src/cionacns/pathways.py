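"""Sensory-to-motor pathway extraction and motif detection.

Minimal pathways are counted in synapses (edges): a "disynaptic" arc runs
sensory -> interneuron -> motor neuron (2 synapses, 1 interneuron).  Gap
junctions are excluded from pathway search by default; an option adds them as
bidirectional edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .model import CellRecord

#: Sensory modality -> roster cell-type codes of the originating neurons.
MODALITY_SOURCES: Mapping[str, tuple[str, ...]] = {
    "light": ("PR-I", "PR-II", "PR-III"),
    "gravity": ("antenna",),
    "coronet": ("coronet",),
    "pns": ("BTN", "RTEN", "ATEN", "DCEN", "VCEN", "pns"),
}


@dataclass(frozen=True)
class PathwayArc:
    """One minimal pathway from a sensory cell to a motor neuron."""

    cells: tuple[str, ...]
    hop_depths_um: tuple[float, ...]
    modality: str | None = None

    @property
    def n_synapses(self) -> int:
        return len(self.cells) - 1


@dataclass
class ArcSearchResult:
    """All minimal-hop arcs between two cell classes; may be unreachable."""

    arcs: list[PathwayArc] = field(default_factory=list)
    min_hops: int | None = None

    @property
    def reachable(self) -> bool:
        return self.min_hops is not None


def _filtered_digraph(
    edge_table: pd.DataFrame,
    min_edge_depth: float = 0.0,
    gap_table: pd.DataFrame | None = None,
) -> nx.DiGraph:
    g = nx.DiGraph()
    for pre, post, depth in edge_table[["pre", "post", "cumulative_depth_um"]].itertuples(
        index=False
    ):
        d = float(depth)
        if d < min_edge_depth or pre == post:
            continue
        if g.has_edge(pre, post):
            g[pre][post]["cumulative_depth_um"] += d
        else:
            g.add_edge(pre, post, cumulative_depth_um=d)
    if gap_table is not None:
        for a, b, depth in gap_table[["pre", "post", "cumulative_depth_um"]].itertuples(
            index=False
        ):
            d = float(depth)
            if d < min_edge_depth or a == b:
                continue
            for u, v in ((a, b), (b, a)):
                if g.has_edge(u, v):
                    g[u][v]["cumulative_depth_um"] += d
                else:
                    g.add_edge(u, v, cumulative_depth_um=d)
    return g


def shortest_arcs(
    edge_table: pd.DataFrame,
    sources: Iterable[str],
    sinks: Iterable[str],
    min_edge_depth: float = 0.0,
    gap_table: pd.DataFrame | None = None,
    modality: str | None = None,
) -> ArcSearchResult:
    """All arcs achieving the minimum hop count from any source to any sink.

    Edges weaker than ``min_edge_depth`` (um of cumulative depth) are removed
    before the search.  Every tying arc is enumerated — ties are never broken.
    Unreachable class pairs return an empty result, not an exception.
    """
    g = _filtered_digraph(edge_table, min_edge_depth, gap_table)
    src = [s for s in set(sources) if s in g]
    snk = set(sinks)
    best: dict[tuple[str, str], int] = {}
    for s in src:
        lengths = nx.single_source_shortest_path_length(g, s)
        for t, d in lengths.items():
            if t in snk and t != s and d >= 1:
                best[(s, t)] = d
    if not best:
        return ArcSearchResult()
    min_hops = min(best.values())
    arcs: list[PathwayArc] = []
    for (s, t), d in sorted(best.items()):
        if d != min_hops:
            continue
        for path in nx.all_shortest_paths(g, s, t):
            depths = tuple(
                g[path[i]][path[i + 1]]["cumulative_depth_um"] for i in range(len(path) - 1)
            )
            arcs.append(PathwayArc(tuple(path), depths, modality))
    arcs.sort(key=lambda a: a.cells)
    return ArcSearchResult(arcs=arcs, min_hops=min_hops)


def modality_subnetwork(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord],
    modality: str,
    weak_depth_threshold: float = 0.5,
    max_hops: int = 4,
) -> pd.DataFrame:
    """Class-level condensation of the subnetwork downstream of one modality.

    Nodes are cell-type classes; an edge class A -> class B sums the depth of
    all member edges.  Only cells reachable from the modality's sensory
    neurons within ``max_hops`` synapses are included, so the condensation
    describes that modality's feed-forward field.  Edges below
    ``weak_depth_threshold`` um are flagged weak (rendered dashed in the
    figures this mirrors).  Total member depth is conserved by construction.
    """
    if modality not in MODALITY_SOURCES:
        raise ValueError(f"unknown modality {modality!r}; known: {sorted(MODALITY_SOURCES)}")
    source_types = MODALITY_SOURCES[modality]
    sources = [cid for cid, c in roster.items() if c.cell_type in source_types]
    g = _filtered_digraph(edge_table)
    reachable: set[str] = set()
    for s in sources:
        if s in g:
            lengths = nx.single_source_shortest_path_length(g, s, cutoff=max_hops)
            reachable.update(lengths)
    class_edges: dict[tuple[str, str], list] = {}
    for u, v, data in g.edges(data=True):
        if u not in reachable or v not in reachable:
            continue
        cu, cv = roster.get(u), roster.get(v)
        if cu is None or cv is None:
            continue
        key = (cu.cell_type, cv.cell_type)
        row = class_edges.setdefault(key, [0, 0.0])
        row[0] += 1
        row[1] += data["cumulative_depth_um"]
    rows = [
        {
            "pre_class": a,
            "post_class": b,
            "n_member_edges": n,
            "cumulative_depth_um": d,
            "weak": d < weak_depth_threshold,
        }
        for (a, b), (n, d) in sorted(class_edges.items())
    ]
    return pd.DataFrame(
        rows, columns=["pre_class", "post_class", "n_member_edges", "cumulative_depth_um", "weak"]
    )


def feedforward_triplets(
    edge_table: pd.DataFrame,
    a_nodes: Iterable[str],
    b_nodes: Iterable[str],
    c_nodes: Iterable[str],
) -> list[tuple[str, str, str]]:
    """Feed-forward motifs a -> b, b -> c with shortcut a -> c across classes.

    Enumerates every node triple (a, b, c) drawn from the three given classes
    for which all three directed edges exist.  Nodes appearing in more than
    one class are allowed, but a triple must use three distinct nodes.
    """
    g = _filtered_digraph(edge_table)
    a_set = [n for n in set(a_nodes) if n in g]
    b_set = set(b_nodes)
    c_set = set(c_nodes)
    motifs: list[tuple[str, str, str]] = []
    for a in a_set:
        succ_a = set(g.successors(a))
        for b in succ_a & b_set:
            if b == a:
                continue
            for c in set(g.successors(b)) & c_set & succ_a:
                if c not in (a, b):
                    motifs.append((a, b, c))
    return sorted(motifs)
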