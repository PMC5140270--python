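"""Synapse-level statistics: totals, polyads, per-neuron budgets, scaling laws.

Reproduces the printed-table arithmetic on a fixture whose totals equal the
reference larva's counts, then measures the same statistics on a freshly
generated stochastic world.
"""

import cionacns as cc

# deterministic fixture with the printed totals
marginal = cc.table1_marginal_connectome()
s = cc.summarize_contacts(marginal)
print("printed-total fixture:")
print(f"  chemical: {s.chemical.total_contacts} contacts / "
      f"{s.chemical.total_sections} sections -> "
      f"mean {s.chemical.mean_sections_per_contact:.1f} sections per synapse")
print(f"  gap junctions: {s.gap.total_contacts} / {s.gap.total_sections} -> "
      f"mean {s.gap.mean_sections_per_contact:.1f}")
print(f"  polyadic: {s.chemical.pct_polyadic:.1f}%  "
      f"unpolarized: {s.chemical.pct_unpolarized:.1f}%  dcv: {s.chemical.pct_dcv:.1f}%")

# stochastic world at the same stated parameters
conn = cc.generate(cc.GeneratorConfig(seed=1))
dist = cc.polyad_distribution(conn)
print("\ngenerated world:")
print(f"  polyad fraction {dist.polyad_fraction:.3f} (generating value 0.107), "
      f"dyad share among polyads {dist.dyad_share:.2f} (0.93)")

comp = cc.compartment_distribution(conn, direction="post")
axo = comp.post_fraction({"axon", "terminal"})
print(f"  fraction of synapses onto axons/terminals: {axo:.2f} "
      "(axo-axonal contact dominates in the larva)")

per_neuron = cc.per_neuron_stats(conn)
stats = per_neuron.attrs["summary"]["presyn_sites"]
print(f"  presynaptic sites per neuron: mean {stats['mean']:.0f}, SD {stats['sd']:.0f}, "
      f"range {stats['min']:.0f}-{stats['max']:.0f}")

fits = cc.fit_scaling(per_neuron)
print(f"  depth ~ synapse count: r^2 = {fits.linear_r2:.2f} (linear)")
print(f"  synapses ~ partners^b: b = {fits.power_exponent:.2f}, r^2 = {fits.power_r2:.2f}")
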