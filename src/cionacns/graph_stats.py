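"""Whole-network statistics over the weighted connectivity graphs.

The conventions follow the NetworkAnalyzer-style suite commonly used for
connectome summaries: shortest paths are hop counts (unweighted by synaptic
depth), the clustering coefficient is computed on the undirected simple graph
with self-loops removed, connected components use weak connectivity for
directed networks, unreachable ordered pairs are excluded from the
characteristic path length and reported as the percentage of pairs that do
have a shortest path, the "average number of neighbours" counts distinct
adjacent nodes ignoring direction, heterogeneity is the coefficient of
variation of that neighbour count, and centralization is
``(n/(n-2)) * (max(k)/(n-1) - density)`` on the undirected view.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .model import CHEMICAL, GAP, Connectome, CellRecord

CNS_REGIONS = ("BV", "neck", "MG", "CNC")


def edge_table_to_graph(edge_table: pd.DataFrame, mode: str = "directed") -> nx.Graph:
    """networkx graph from an edge table, with depth as edge attribute."""
    g = nx.DiGraph() if mode == "directed" else nx.Graph()
    for row in edge_table.itertuples(index=False):
        w = float(row.cumulative_depth_um)
        if g.has_edge(row.pre, row.post):
            g[row.pre][row.post]["cumulative_depth_um"] += w
        else:
            g.add_edge(row.pre, row.post, cumulative_depth_um=w)
    return g


def cns_nodes(roster: Mapping[str, CellRecord] | Iterable[CellRecord]) -> set[str]:
    """Ids of CNS neurons (brain vesicle, neck, motor ganglion, nerve cord)."""
    cells = roster.values() if isinstance(roster, Mapping) else roster
    return {c.cell_id for c in cells if c.is_neuron and c.region in CNS_REGIONS}


@dataclass
class NetworkStatReport:
    """Table-2-style statistic suite for one network."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float | None
    n_connected_components: int
    diameter: int
    radius: int
    n_shortest_paths: int
    pct_pairs_with_shortest_path: float
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float
    centralization: float
    n_self_loops: int
    n_multi_edge_pairs: int | None = None

    def to_dict(self) -> dict:
        return {
            "Clustering coefficient": self.clustering_coefficient,
            "Connected components": self.n_connected_components,
            "Network diameter": self.diameter,
            "Radius": self.radius,
            "Shortest paths": self.n_shortest_paths,
            "Shortest paths (%)": self.pct_pairs_with_shortest_path,
            "Characteristic path length": self.characteristic_path_length,
            "Average number of neighbours": self.avg_neighbors,
            "Number of nodes": self.n_nodes,
            "Network density": self.density,
            "Network heterogeneity": self.heterogeneity,
            "Number of self-loops": self.n_self_loops,
            "Multi-edge node pairs": self.n_multi_edge_pairs,
            "Network centralisation": self.centralization,
        }


def network_stats(
    edge_table: pd.DataFrame,
    mode: str = "directed",
    nodes: Iterable[str] | None = None,
) -> NetworkStatReport:
    """Compute the full statistic suite for one edge table.

    ``mode`` is ``"directed"`` for chemical-synapse networks or
    ``"undirected"`` for gap-junction networks; shortest-path statistics
    respect edge direction in directed mode.  ``nodes`` restricts the network
    to a subset (e.g. CNS neurons only) before any statistic is computed.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"unknown mode {mode!r}")
    g = edge_table_to_graph(edge_table, mode)
    if nodes is not None:
        keep = set(nodes)
        g = g.subgraph([n for n in g.nodes if n in keep]).copy()
        g.add_nodes_from(keep)  # scope nodes without edges stay as isolates
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph: no nodes survive the scope filter")

    n = g.number_of_nodes()
    self_loops = [u for u, v in nx.selfloop_edges(g)]

    # undirected simple view without self-loops, for neighbour-based statistics
    u = nx.Graph()
    u.add_nodes_from(g.nodes)
    u.add_edges_from((a, b) for a, b in g.to_undirected().edges if a != b)

    clustering = nx.average_clustering(u) if n >= 3 else None

    if mode == "directed":
        n_components = nx.number_weakly_connected_components(g)
    else:
        n_components = nx.number_connected_components(g)

    # hop-count distances over ordered pairs (u != v)
    search = g if mode == "directed" else u
    finite = []
    eccentricities = []
    for src, dists in nx.all_pairs_shortest_path_length(search):
        reach = [d for t, d in dists.items() if t != src]
        finite.extend(reach)
        if reach:
            eccentricities.append(max(reach))
    n_pairs = n * (n - 1)
    n_finite = len(finite)
    diameter = max(finite) if finite else 0
    radius = min(eccentricities) if eccentricities else 0
    cpl = float(np.mean(finite)) if finite else float("nan")

    degrees = np.array([u.degree(v) for v in u.nodes], dtype=float)
    avg_neighbors = float(degrees.mean())
    m_simple = u.number_of_edges()
    if mode == "directed":
        m_dir = sum(1 for a, b in g.edges if a != b)
        density = m_dir / n_pairs if n_pairs else float("nan")
    else:
        density = 2.0 * m_simple / n_pairs if n_pairs else float("nan")
    density_u = 2.0 * m_simple / n_pairs if n_pairs else float("nan")
    mean_k = degrees.mean()
    heterogeneity = float(degrees.std(ddof=0) / mean_k) if mean_k > 0 else float("nan")
    if n > 2:
        centralization = float((n / (n - 2)) * (degrees.max() / (n - 1) - density_u))
    else:
        centralization = float("nan")

    return NetworkStatReport(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        clustering_coefficient=clustering,
        n_connected_components=n_components,
        diameter=diameter,
        radius=radius,
        n_shortest_paths=n_finite,
        pct_pairs_with_shortest_path=100.0 * n_finite / n_pairs if n_pairs else float("nan"),
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        density=density,
        heterogeneity=heterogeneity,
        centralization=centralization,
        n_self_loops=len(self_loops),
    )


def degree_table(edge_table: pd.DataFrame) -> pd.DataFrame:
    """Per-node in-degree, out-degree, undirected neighbour count, self-loop flag.

    Degrees count aggregated directed edges (one per ordered pair); a
    self-loop contributes once to both the in- and out-degree of its node.
    """
    nodes = sorted(set(edge_table["pre"]) | set(edge_table["post"]))
    out_deg = {v: 0 for v in nodes}
    in_deg = {v: 0 for v in nodes}
    neighbors: dict[str, set] = {v: set() for v in nodes}
    self_loop = {v: False for v in nodes}
    for pre, post in edge_table[["pre", "post"]].itertuples(index=False):
        out_deg[pre] += 1
        in_deg[post] += 1
        if pre == post:
            self_loop[pre] = True
        else:
            neighbors[pre].add(post)
            neighbors[post].add(pre)
    return pd.DataFrame(
        {
            "in_degree": [in_deg[v] for v in nodes],
            "out_degree": [out_deg[v] for v in nodes],
            "n_neighbors": [len(neighbors[v]) for v in nodes],
            "self_loop": [self_loop[v] for v in nodes],
        },
        index=pd.Index(nodes, name="cell_id"),
    )


def multi_edge_pairs(
    connectome: Connectome, kind: str = CHEMICAL, nodes: Iterable[str] | None = None
) -> int:
    """Ordered pairs connected by more than one distinct annotated contact.

    Works on raw contacts (not the aggregated edge table): a polyadic contact
    contributes one count to each of its (pre, post) pairs.  Gap-junction
    pairs are counted on the canonical unordered pair.
    """
    keep = set(nodes) if nodes is not None else None
    mult: dict[tuple[str, str], int] = {}
    for c in connectome.contacts_of_kind(kind):
        if kind == GAP:
            pairs = [c.canonical_gap_pair()]
        else:
            pairs = [(c.pre_cell, t) for t in c.post_targets]
        for pair in pairs:
            if keep is not None and (pair[0] not in keep or pair[1] not in keep):
                continue
            mult[pair] = mult.get(pair, 0) + 1
    return sum(1 for v in mult.values() if v >= 2)
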