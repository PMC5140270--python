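"""Brute-force reference implementations used as independent oracles.

Everything here is written with plain dictionaries, sets and loops — no
networkx, no pandas — so the package's graph statistics can be checked
against direct transcriptions of the definitions.
"""

from __future__ import annotations

import math


def bfs_distances(adj: dict[str, set[str]], src: str) -> dict[str, int]:
    dist = {src: 0}
    frontier = [src]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def undirected_simple(edges: list[tuple[str, str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set())
        adj.setdefault(b, set())
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def oracle_clustering(und_adj: dict[str, set[str]]) -> float:
    """Average local clustering: existing / possible edges between neighbours."""
    vals = []
    for v, nbrs in und_adj.items():
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = 0
        nbr_list = sorted(nbrs)
        for i in range(k):
            for j in range(i + 1, k):
                if nbr_list[j] in und_adj[nbr_list[i]]:
                    links += 1
        vals.append(2.0 * links / (k * (k - 1)))
    return sum(vals) / len(vals)


def oracle_components(nodes: list[str], edges: list[tuple[str, str]]) -> int:
    """Connected components, ignoring edge direction."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(v) for v in nodes})


def oracle_network_stats(
    nodes: list[str], edges: list[tuple[str, str]], directed: bool = True
) -> dict:
    """Direct transcription of every statistic definition, by exhaustion."""
    n = len(nodes)
    und = undirected_simple(edges)
    for v in nodes:
        und.setdefault(v, set())
    if directed:
        search: dict[str, set[str]] = {v: set() for v in nodes}
        for a, b in edges:
            if a != b:
                search[a].add(b)
    else:
        search = und

    finite = []
    eccentricities = []
    for src in nodes:
        dists = bfs_distances(search, src)
        reach = [d for t, d in dists.items() if t != src]
        finite.extend(reach)
        if reach:
            eccentricities.append(max(reach))

    degrees = [len(und[v]) for v in nodes]
    mean_k = sum(degrees) / n
    sd_k = math.sqrt(sum((k - mean_k) ** 2 for k in degrees) / n)
    m_simple = sum(len(s) for s in und.values()) // 2
    n_pairs = n * (n - 1)
    if directed:
        m_dir = len({(a, b) for a, b in edges if a != b})
        density = m_dir / n_pairs if n_pairs else float("nan")
    else:
        density = 2.0 * m_simple / n_pairs if n_pairs else float("nan")
    density_u = 2.0 * m_simple / n_pairs if n_pairs else float("nan")
    return {
        "n_nodes": n,
        "clustering_coefficient": oracle_clustering(und) if n >= 3 else None,
        "n_connected_components": oracle_components(nodes, edges),
        "diameter": max(finite) if finite else 0,
        "radius": min(eccentricities) if eccentricities else 0,
        "n_shortest_paths": len(finite),
        "pct_pairs_with_shortest_path": 100.0 * len(finite) / n_pairs if n_pairs else float("nan"),
        "characteristic_path_length": sum(finite) / len(finite) if finite else float("nan"),
        "avg_neighbors": mean_k,
        "density": density,
        "heterogeneity": sd_k / mean_k if mean_k > 0 else float("nan"),
        "centralization": (n / (n - 2)) * (max(degrees) / (n - 1) - density_u)
        if n > 2
        else float("nan"),
        "n_self_loops": len({a for a, b in edges if a == b}),
    }


def oracle_all_shortest_paths(
    adj: dict[str, set[str]], src: str, dst: str
) -> list[tuple[str, ...]]:
    """Every minimum-hop path src -> dst, by exhaustive layered enumeration."""
    dist = bfs_distances(adj, src)
    if dst not in dist or dst == src:
        return []
    target_d = dist[dst]
    paths = []

    def extend(path):
        u = path[-1]
        if u == dst:
            paths.append(tuple(path))
            return
        if len(path) - 1 >= target_d:
            return
        for v in sorted(adj.get(u, ())):
            if dist.get(v, math.inf) == len(path):
                extend(path + [v])

    extend([src])
    return paths


def oracle_reciprocity(edges: list[tuple[str, str]]) -> float:
    es = {(a, b) for a, b in edges if a != b}
    pairs = {(min(a, b), max(a, b)) for a, b in es}
    recip = sum(1 for a, b in pairs if (a, b) in es and (b, a) in es)
    return recip / len(pairs)
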