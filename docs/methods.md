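# Methods

This note records the models, conventions and numerical choices behind
`cionacns`, in the package's own terms: what each quantity means, which
parameters matter, what the synthetic generator does and does not emulate,
and where design decisions were genuinely open.

## 1. Data model

A connectome is a roster of cells plus a list of annotated contacts and a
section-thickness schedule.

**Cells.** Each cell carries a controlled type code (photoreceptor classes
PR-I/II/III, coronet, antenna, brain-vesicle interneurons and relay classes,
motor-ganglion interneurons MGIN, motor neurons MN, ACINs, etc.), a region
(brain vesicle BV, neck, motor ganglion MG, caudal nerve cord CNC, PNS,
muscle), a side, and optionally a nucleus position `(section, x, y)`.
Muscle cells, the basal lamina and "space" (no apparent postsynaptic
partner) are modelled as postsynaptic-only pseudo-cells with
`is_neuron=False`; this makes synapses onto them representable, countable
and excludable with the standard exclusion keywords (`Mu`, `bm`, `space`,
plus `Ep` for ependymal cells).

**Side assignment.** A dorso-ventral midline through the neural canal is
given as an x-coordinate (constant, per-section mapping, or callable).
Nuclei strictly left/right of the line get that side; nuclei within a
declared nucleus radius of the line are midline; cells without a traced
nucleus are `unassigned` (with no guess). Smaller x is the animal's left by
convention.

**Contacts and cumulative depth.** A contact records its kind (chemical or
gap), presynaptic cell, ordered postsynaptic targets (≥2 for polyads;
exactly one, unordered, for gap junctions), 0-based first section, section
count, and optional per-section thickness profile. The strength proxy is
the cumulative depth: the per-section thickness summed over the closed span
`[first, first+n−1]`, in µm. Summing per-section values (rather than
multiplying by a single scalar) makes contacts that straddle the 60/70 nm or
70/100 nm zone boundaries exact. When a contact has no explicit profile the
connectome's thickness schedule resolves it; the default schedule is the
reference series (sections 0–3374 at 60 nm, 3375–4734 at 70 nm, 4735–6927 at
100 nm).

**Edge aggregation.** `build_edge_table` emits one row per ordered (pre,
post) pair with the contact count, summed sections and summed depth. Every
polyadic contact contributes its full span and depth to each surviving
target ("all connections are plotted" semantics). Exclusion keywords drop
individual targets; `min_sections` drops whole contacts before aggregation.
Gap junctions aggregate on the canonical pair (lexicographically smaller
cell first); gap thresholds (e.g. >0.06 µm, >0.12 µm) are parameters of the
caller, never constants.

**Unpolarized contacts** (vesicles on both sides of the cleft) are stored
once with the annotated primary direction plus a flag — the headline contact
totals count them once. The optional `unpolarized="mirror"` mode of
`build_edge_table` additionally emits the reversed direction with the same
span and depth. We chose full rather than halved depth for the mirrored
direction because the annotation describes one anatomical apposition that is
functionally bidirectional, not two half-sized contacts; halving would make
the mirrored view's total depth disagree with the anatomical total.

## 2. Contact statistics

`summarize_contacts` computes, per kind: totals of contacts and sections,
mean sections per contact (total ratio, exact), the >1-section subset and
its mean, and the unpolarized / polyadic / dense-core-vesicle percentages.
A contact survives `exclusions` if at least one target survives. Reported
percentages and means are rounded half-up to one decimal (matching printed
tables); full precision is kept internally.

`per_neuron_stats` tabulates per-neuron presynaptic sites (with and without
neuromuscular junctions), received synapses, gap-junction contacts, distinct
partner counts and total presynaptic depth. The population denominator is
CNS neurons with ≥1 presynaptic site; bipolar tail neurons can be added via
`include_types=("BTN",)` since the published denominator (177 CNS neurons
vs 181 with BTNs) is ambiguous — neither reading is asserted. SD is the
population SD (divisor n) by default, configurable via `ddof`.

`fit_scaling` fits (a) total presynaptic depth vs synapse count by ordinary
least squares on raw values and (b) the power law S = a·P^b between synapse
count S and postsynaptic partner count P by least squares on log–log values
(r² reported on the log scale). OLS-on-logs rather than a nonlinear or MLE
fit matches how such r² values are conventionally obtained for this
relationship. Rows with non-positive S or P are excluded with a warning.

## 3. Network statistics

Conventions (validated against brute-force oracles on random graphs ≤20
nodes in the test suite):

* shortest paths are hop counts, not depth-weighted — the observed path
  lengths (~2.7 between neurons) are consistent with hops;
* clustering is the average local clustering coefficient on the undirected
  simple graph with self-loops removed;
* connected components use weak connectivity for directed networks;
* unreachable ordered pairs are excluded from the characteristic path length
  and reported via the reachable-pair percentage and count;
* the average number of neighbours counts distinct adjacent nodes ignoring
  direction; heterogeneity is SD(k)/mean(k) of that count; centralization is
  (n/(n−2))·(max k/(n−1) − density) on the undirected view;
* density uses directed convention m/(n(n−1)) for directed mode;
* self-loops are counted separately and excluded from clustering and pair
  statistics; multi-edge pairs are counted from raw contacts (ordered pairs
  with ≥2 distinct contacts).

A caveat uncovered by testing: with L averaged over *reachable* pairs only,
adding an edge can legitimately increase L (it makes distant pairs
reachable). The true monotonicity invariant — every pairwise distance is
non-increasing under edge addition — is what the suite asserts.

The scope argument restricts the node set before any statistic; scope nodes
without surviving edges remain as isolates (they count as components and
dilute clustering), matching how a "CNS neurons only" subnetwork with an
isolated profile is reported.

## 4. Reciprocity

The reciprocity proportion is the fraction of unordered neuron pairs, among
pairs with at least one directed edge, that have edges in both directions.
Pairs involving muscle/basal-lamina pseudo-cells are excluded by default
(they are exclusively postsynaptic and can never be reciprocal; including
them would only deflate the proportion), available behind the roster
argument for sensitivity. Self-loops are excluded. Per pair, the extent is
computed from the larger direction (so extent ∈ [0.5, 1.0], and the two
directional extents sum to 1); the geometric mean √(D_fwd·D_bwd) is NaN for
one-way pairs.

Whether the published 0.39 denominator uses all contacts or only >1-section
contacts is not stated; both are computable (`min_sections` at edge-table
construction), and the all-contact version is the default benchmark.

## 5. Asymmetry

Neuromuscular L:R ratios pool the dorsal and medial muscle bands per side
(they are electrically coupled by gap junctions and act as one unit); the
muscle side is the target cell's own side attribute. Printed ratio pairs
use largest-remainder rounding so they sum to exactly 100. Relay laterality
reports left vs right shares of a source class's output into a target
region, by contact count and by depth, with midline targets tallied
separately. Side-sorted matrices order rows left→midline→right and columns
right→midline→left, so the quadrants read left→right, left→left,
right→left, right→right, preserving rostro-caudal order within blocks;
sideless pseudo-cells (pooled muscle, basal lamina) move to trailing
rows/columns, while a sideless *neuron* is an error. Homolog comparison
(`side_diff`) takes an explicit left↔right bijection — pairing is supplied,
never inferred — and partitions within-set edges into both-sides (with
left/right weight ratio), left-only and right-only. No significance testing
is performed: the data model describes a single specimen.

## 6. Pathways

Arc length is counted in synapses: disynaptic = sensory → interneuron →
motor neuron. All arcs achieving the global minimum hop count are
enumerated; ties are never broken. `min_edge_depth` prunes weak edges
before the search (default 0 — no evidence the published minimal arcs were
thresholded; the monotonicity of minimal hops in the threshold is a tested
property). Gap junctions are excluded by default and can be added as
bidirectional edges. Modality condensations group cells by type code
within the ≤`max_hops` feed-forward field of a modality's sensory neurons,
summing member-edge depth (conserved by construction) and flagging edges
below a configurable weak-edge threshold.

## 7. Synthetic generator

The generator's defaults are the stated world of the reference larva; they
are never tuned toward test outcomes.

* **Roster.** Curated per-type counts hitting the published sided census:
  BV 72/14/57, neck 1/0/1, MG 12/1/12 (5 MN + 3 MGIN + 1 ddN + 3 AMG per
  side), CNC 3/0/5 — all-CNS 88 left / 15 centre / 75 right — plus 4 BTNs,
  24 muscle cells in dorsal/medial/ventral bands, ependymal cells and the
  basal-lamina/"space" pseudo-cells. Nucleus x-positions are drawn strictly
  on the declared side of the midline (x=100), so geometric side assignment
  round-trips the census.
* **Per-neuron synapse counts.** Negative binomial with mean 49, SD 61
  (variance exceeds the mean, ruling out a Poisson), parameterised by
  r = µ²/(σ²−µ), truncated below at 1.
* **Partner coupling.** A neuron with S scaffold contacts gets
  P = round((S/a)^(1/b)) distinct partners (defaults a=4.5, b=0.8), each
  with ≥1 contact, the rest multinomially spread.
* **Section spans.** Truncated geometric distributions: chemical p=2/7
  capped at 29 sections (exact truncated mean 3.49), NMJ p=0.2 capped at 65,
  gap p=1/1.8 capped at 55 — most spans <10 sections, as observed.
* **Polyads and vesicles.** Every chemical contact is polyadic with
  probability 0.107 (dyad with probability 0.93 among polyads, else triad),
  unpolarized with 0.052, dense-core-vesicle-bearing with 0.08.
* **Reciprocity.** Induced post hoc: after all pair-creating steps, each
  one-way neuron pair receives a reverse contact with probability
  q = (0.39·n_pairs − n_reciprocal)/n_one-way, which is exact in
  expectation. Polyad extras for post-scaffold contacts (mirrors, basal
  lamina, NMJ) are drawn from the presynaptic cell's *existing* partners
  (or same-side muscle for NMJs) so they never create new neuron pairs and
  cannot bias the calibration. This mirroring is a transparency-over-realism
  choice: a degree-corrected null would be less interpretable.
* **Neuromuscular junctions.** Per motor pair, junction totals and left
  shares default to the per-pair tallies of the reference larva
  (599/0.40, 482/0.46, 70/0.60, 75/0.60, 36/0.58); each junction lands on a
  left-side muscle cell with the configured probability, dorsal band with
  probability 0.7.
* **Gap junctions.** Per-neuron counts from a negative binomial (mean 13,
  SD 23) halved (each contact joins two cells), partners uniform.
* **Determinism.** One numpy `default_rng(seed)` (PCG64) drives everything;
  identical config + seed gives byte-identical contact tables.

**What the generator does not emulate** — hence what a green test does and
does not establish: no spatial structure beyond valid section indices (axon
trajectories, neuropil geometry); partner choice is uniform rather than
layered, so minimal sensory→motor arcs in generated worlds can be
monosynaptic, unlike the real circuit (the deterministic `layered_fixture`
covers layered-pathway behaviour); no inter-contact correlations (large
contacts do not cluster on specific partners — independence is stated in the
fixture manifest); and measured per-neuron totals sit slightly above the
scaffold mean because reciprocity mirrors, NMJs and basal-lamina contacts
add to presynaptic counts. The mirroring also means the measured
partner-coupling exponent on a full generated world is biased above the
scaffold's b (mirrored contacts add synapses and partners one-for-one);
exponent-recovery checks therefore use the direct scaling population
(`scaling_population`), which generates the neuron-level S = a·P^b + noise
relationship itself.

A deterministic companion, `table1_marginal_connectome`, realises the
printed contact totals exactly (8617 chemical / 30163 sections / 6618 over
one section / 922 polyads as 858 dyads + 64 triads / 448 unpolarized / 689
dcv; 3205 gap / 5765 sections / 1206 over one section) for exact-arithmetic
tests; span multisets (1999×1, 4926×4, 1692×5 chemical; 1999×1, 1058×3,
148×4 gap) are the simplest integer solutions consistent with those totals
and the published span caps.

## 8. Numerical and serialization choices

* Percentages/means print at one decimal, rounded half-up; ratios print as
  largest-remainder integer pairs summing to 100.
* Writers are deterministic (fixed column orders, `\n` line endings).
  Floats serialize with 12 significant digits: 6 digits (a plausible
  printed-table convention) would violate the 1e-9 µm matrix round-trip
  guarantee, and the guarantee wins.
* Matrix labels are `cell_id|type`; readers strip the type suffix.
  Deposited spreadsheet matrices are ingested after a one-time conversion
  to CSV (first sheet, first row/column as labels, values in µm) —
  conversion notes are deliberately user-editable here.
* Exact binomial 95% confidence intervals (scipy) are the acceptance bands
  for stochastic recovery tests; stochastic checks pool ten fixed seeds
  (0–9) so Monte Carlo error is small relative to the band.

## 9. Known limitations

* Single-specimen semantics: no inter-individual variability model and no
  statistical tests of asymmetry.
* The generator's uniform partner choice produces denser, shallower
  networks than the real circuit (higher clustering, shorter path lengths);
  whole-network statistics of generated worlds are therefore checked
  against oracles, not against published network values. Published-value
  benchmarks run only against the deposited matrix when its CSV conversion
  is present under `data/`.
* Table-1-style totals in the source material disagree between prose and
  table (8768 vs 8617 synapses; 2105 vs 3205 gap junctions); the model
  stores whatever the input contains and the marginal fixture follows the
  table, since the acceptance arithmetic quotes the table's pairs.
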