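"""Minimal sensory-to-motor pathways and feed-forward motifs.

Arc length is counted in synapses: a disynaptic arc passes through one
interneuron, a trisynaptic arc through two.  All tying minimal arcs are
enumerated, never broken arbitrarily.
"""

import cionacns as cc

# a hand-built layered circuit: photoreceptors -> relay neurons -> motor side
conn = cc.layered_fixture()
chem = cc.build_edge_table(conn)
res = cc.shortest_arcs(
    chem,
    cc.select_cells(conn, cell_type="PR-I"),
    cc.select_cells(conn, cell_type="MN"),
)
print(f"layered circuit: minimal light->motor arc = {res.min_hops} synapses "
      f"({len(res.arcs)} tying arc(s))")
for arc in res.arcs:
    hops = " -> ".join(arc.cells)
    depths = ", ".join(f"{d:.2f}" for d in arc.hop_depths_um)
    print(f"  {hops}   per-hop depths (um): {depths}")

# raising the edge-depth threshold prunes weak shortcuts and lengthens arcs
weak_pruned = cc.shortest_arcs(
    chem,
    cc.select_cells(conn, cell_type="PR-I"),
    cc.select_cells(conn, cell_type="MN"),
    min_edge_depth=0.15,
)
print(f"with edges <0.15 um removed the minimal arc has {weak_pruned.min_hops} synapses")

# class-level condensation of the light pathway on a generated world
world = cc.generate(cc.GeneratorConfig(seed=1))
et = cc.build_edge_table(world, exclusions=("Mu", "bm", "Ep", "space"))
net = cc.modality_subnetwork(et, world.cells, "light", weak_depth_threshold=1.0)
strong = net[~net["weak"]].nlargest(5, "cumulative_depth_um")
print("\nstrongest class-level edges downstream of the photoreceptors:")
for row in strong.itertuples(index=False):
    print(f"  {row.pre_class} -> {row.post_class}: {row.cumulative_depth_um:.1f} um "
          f"over {row.n_member_edges} member edges")

motifs = cc.feedforward_triplets(
    cc.build_edge_table(conn),
    cc.select_cells(conn, cell_type="PR-I"),
    cc.select_cells(conn, cell_type="prRN"),
    cc.select_cells(conn, cell_type="MGIN"),
)
print(f"\nfeed-forward triplets (PR -> RN -> MGIN with PR -> MGIN shortcut): {len(motifs)}")
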