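"""Whole-network statistics of the chemical and gap-junction graphs.

Edges are weighted by cumulative synaptic depth (um); shortest paths count
synaptic hops.  The suite mirrors the statistics conventionally reported for
connectomes: clustering, path length, reachable-pair share, degree summary,
heterogeneity and centralization.
"""

import cionacns as cc

conn = cc.generate(cc.GeneratorConfig(seed=1))

chem = cc.build_edge_table(conn, kind="chemical")
gap = cc.build_edge_table(conn, kind="gap")

full = cc.network_stats(chem, mode="directed")
cns = cc.network_stats(chem, mode="directed", nodes=cc.cns_nodes(conn.cells))
gj = cc.network_stats(gap, mode="undirected")

for name, r in (("chemical, full", full), ("chemical, CNS only", cns), ("gap junctions", gj)):
    print(f"{name}:")
    print(f"  nodes {r.n_nodes}, components {r.n_connected_components}, "
          f"self-loops {r.n_self_loops}")
    print(f"  clustering {r.clustering_coefficient:.3f}, "
          f"path length {r.characteristic_path_length:.3f} hops, "
          f"diameter {r.diameter}")
    print(f"  {r.pct_pairs_with_shortest_path:.0f}% of ordered pairs connected "
          f"[{r.n_shortest_paths}], avg neighbours {r.avg_neighbors:.1f}")

print(f"\nordered pairs with >1 distinct contact: {cc.multi_edge_pairs(conn)}")
deg = cc.degree_table(chem)
hub = deg["out_degree"].idxmax()
print(f"highest out-degree cell: {hub} "
      f"({deg.loc[hub, 'out_degree']} postsynaptic partners)")
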