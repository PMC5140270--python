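"""Build a synthetic connectome, validate it, and write the interchange files.

The generator emulates the annotated serial-section EM series of an ascidian
tadpole larva: a sided cell roster, chemical synapses (including polyads and
neuromuscular junctions), and putative gap junctions, all with per-section
thickness bookkeeping.
"""

from pathlib import Path

import cionacns as cc

out = Path("scratch/example01")
out.mkdir(parents=True, exist_ok=True)

conn = cc.generate(cc.GeneratorConfig(seed=1))
findings = cc.validate(conn)
print(f"cells: {len(conn.cells)}  contacts: {len(conn.contacts)}")
print(f"validation findings: {len(findings)}  (0 means structurally well-formed)")

census = cc.sided_counts(conn.cells).attrs["totals"]["all_CNS"]
print(f"CNS neurons by side  left: {census['left']}  centre: {census['midline']}  "
      f"right: {census['right']}")
print("  (the reference larva counts 88 left, 15 centre, 75 right)")

cc.write_contacts(conn, out / "contacts.csv")
cc.write_roster(conn, out / "roster.csv")
cc.write_thickness_schedule(conn.thickness_schedule, out / "thickness.yaml")

# a contact's strength proxy is its cumulative depth: sections x thickness
c = conn.contacts[0]
depth = cc.contact_depth(c, conn.thickness_schedule)
print(f"first contact spans {c.n_sections} sections -> cumulative depth {depth:.2f} um")
print(f"files written under {out}/")
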