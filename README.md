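# cionacns

Quantitative analysis of the larval *Ciona intestinalis* CNS connectome —
from an annotated serial-section EM contact table to weighted connectivity
matrices, synapse statistics, network statistics, reciprocity and left/right
asymmetry measures, and shortest sensory→motor pathways.

## Who this is for

Connectomics groups working with serial-section EM annotations of small
nervous systems (the ascidian tadpole larva, *C. elegans*-scale circuits).
The package takes two tables — a **cell roster** (id, type, region, side,
nucleus position) and a **contact table** (presynaptic cell, one or more
postsynaptic targets, section span, per-section thickness, vesicle and
compartment annotations) — and computes the full statistic suite such a study
reports. A seeded synthetic-connectome generator reproduces the statistical
structure of the reference larva so every analysis is testable without any
data download.

## The quantities at the core

* **Cumulative synaptic depth** — the strength proxy for a contact spanning
  sections *s*…*s+n−1*:  D = Σₖ t(k) / 1000 µm, where t(k) is the thickness
  (nm) of section k (60/70/100 nm zones along the A–P axis). Edge weight of
  an ordered pair (i→j) is the sum over its contacts; a polyadic contact
  (dyad, triad) contributes its full depth to *every* postsynaptic target.
* **Network statistics** — on the directed chemical graph and undirected
  gap-junction graph: average clustering coefficient C, characteristic path
  length L (mean hop count over reachable ordered pairs), reachable-pair
  share, average neighbour count ⟨k⟩, density, heterogeneity SD(k)/⟨k⟩, and
  centralization (n/(n−2))·(max k/(n−1) − density).
* **Reciprocity** — the fraction of connected neuron pairs wired in both
  directions; per pair, the extent r = D_fwd/(D_fwd+D_bwd) and geometric
  mean g = √(D_fwd·D_bwd).
* **Left/right asymmetry** — sided cell censuses, neuromuscular L:R ratios
  per motor-neuron pair (largest-remainder percentages summing to 100),
  relay-class laterality into the motor ganglion, side-sorted connectivity
  matrices, and edge-by-edge comparison of homologous left/right subnetworks.
* **Pathways** — all minimal-hop sensory→motor arcs (disynaptic = 2
  synapses), class-level condensations per sensory modality, and
  feed-forward triplet motifs.

## Worked example

```python
import cionacns as cc

conn = cc.generate(cc.GeneratorConfig(seed=1))   # synthetic stated world
chem = cc.build_edge_table(conn, kind="chemical")

census = cc.sided_counts(conn.cells).attrs["totals"]["all_CNS"]
print(census["left"], census["midline"], census["right"])
# 88 15 75      <- CNS neurons by side, matching the reference census

print(round(cc.reciprocity_proportion(chem, conn.cells), 3))
# 0.396         <- fraction of connected neuron pairs wired both ways (target 0.39)

dist = cc.polyad_distribution(conn)
print(round(dist.polyad_fraction, 3), round(dist.dyad_share, 2))
# 0.11 0.93     <- polyadic contact share and dyad share among polyads

lr = cc.nmj_lr_ratio(conn, "MN2")
print(lr.ratio_by_count)
# (48, 52)      <- MN2 pair neuromuscular input, left:right (configured 46:54)
```

The deterministic fixture `cc.table1_marginal_connectome()` reproduces the
printed contact totals exactly: 8617 chemical contacts over 30163 sections
(mean 3.5 sections/synapse, 10.7% polyadic) and 3205 gap-junction contacts
over 5765 sections (mean 1.8). See `examples/` for one narrative script per
capability (validation/IO, synapse statistics, network statistics,
reciprocity & asymmetry, pathways); each prints the numbers it computes with
a line on what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Recomputes the whole pipeline from scratch on the seeded synthetic world —
generation, validation, the printed-total fixture summary, network
statistics (full / CNS-only / gap), reciprocity, sided censuses,
neuromuscular ratios, scaling fits and pathway search — and writes the JSON
result file, with a human-readable run log alongside
(`results/acceptance.log.json`).

## Using real annotation data

Readers accept the package's CSV schemas (`read_contacts`, `read_roster`,
`read_matrix` for square depth matrices with `cell_id|type` labels,
`read_thickness_schedule` for YAML/JSON zone lists). Deposited spreadsheet
matrices should be converted to CSV once (sheet and header conventions are
recorded in `docs/methods.md`); benchmark tests against the deposited
whole-brain matrix activate automatically when
`data/fig16_chemical_matrix.csv` is present. `export_graphml` writes
GraphML for external viewers.
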