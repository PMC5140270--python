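"""Seeded generator of synthetic connectomes.

The generator emulates the statistical structure of a single annotated
serial-section EM series of an ascidian tadpole larva so that every analysis
module is testable without any data download:

* a sided cell roster (left/centre/right census per region matching the
  reference larva: 88 left, 15 centre, 75 right CNS neurons), plus muscle
  cells, basal lamina, ependymal and "space" pseudo-cells;
* per-neuron presynaptic-site counts drawn from a negative binomial with
  mean 49 and SD 61 (the SD exceeds the mean, ruling out a Poisson);
* the partner coupling S = a * P^b between a neuron's synapse count S and its
  postsynaptic partner count P (default exponent 0.8);
* contact section spans from truncated geometric distributions (mass
  concentrated below 10 sections; chemical synapses capped at 29 sections,
  neuromuscular junctions at 65, gap junctions at 55);
* a 10.7% polyad probability with 93% dyads among polyads, 5.2% unpolarized
  and 8% dense-core-vesicle contacts;
* a target reciprocity proportion of 0.39, induced by post-hoc edge mirroring
  with an analytically chosen probability;
* per-motor-pair neuromuscular left:right skews (defaults from the reference
  larva's per-pair junction tallies, e.g. 46:54 for the MN2 pair).

Identical config + seed always produces identical output (numpy PCG64 via
``numpy.random.default_rng``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import (
    CHEMICAL,
    GAP,
    CellRecord,
    Connectome,
    ContactRecord,
    ThicknessSchedule,
)
from . import io as cio

# (cell_type, region, side, count) — curated to the reference larva's sided
# census: BV 72/14/57, neck 1/0/1, MG 12/1/12, CNC 3/0/5 (all-CNS 88/15/75).
DEFAULT_ROSTER_SPEC: tuple[tuple[str, str, str, int], ...] = (
    # brain vesicle, left (72)
    ("coronet", "BV", "left", 17),
    ("prRN", "BV", "left", 8),
    ("antRN", "BV", "left", 7),
    ("BVIN", "BV", "left", 40),
    # brain vesicle, centre (14)
    ("antenna", "BV", "midline", 2),
    ("BVIN", "BV", "midline", 12),
    # brain vesicle, right (57)
    ("PR-I", "BV", "right", 23),
    ("PR-II", "BV", "right", 7),
    ("PR-III", "BV", "right", 7),
    ("trIN", "BV", "right", 3),
    ("bipolar-IN", "BV", "right", 2),
    ("aaIN", "BV", "right", 3),
    ("pr-AMG RN", "BV", "right", 6),
    ("RN", "BV", "right", 2),
    ("antRN", "BV", "right", 2),
    ("ant-corRN", "BV", "right", 1),
    ("BVIN", "BV", "right", 1),
    # neck (1 left, 1 right)
    ("neck-IN", "neck", "left", 1),
    ("neck-IN", "neck", "right", 1),
    # motor ganglion (12 per side + 1 centre)
    ("MN", "MG", "left", 5),
    ("MGIN", "MG", "left", 3),
    ("ddN", "MG", "left", 1),
    ("AMG", "MG", "left", 3),
    ("AMG", "MG", "midline", 1),
    ("MN", "MG", "right", 5),
    ("MGIN", "MG", "right", 3),
    ("ddN", "MG", "right", 1),
    ("AMG", "MG", "right", 3),
    # caudal nerve cord (3 left, 5 right)
    ("ACIN", "CNC", "left", 2),
    ("midtail", "CNC", "left", 1),
    ("ACIN", "CNC", "right", 1),
    ("PMGN", "CNC", "right", 2),
    ("midtail", "CNC", "right", 2),
    # peripheral nervous system (bipolar tail neurons)
    ("BTN", "PNS", "left", 2),
    ("BTN", "PNS", "right", 2),
    # muscle cells (dorsal/medial bands innervated; ventral present but minor)
    ("muscle", "muscle", "left", 0),  # placeholder, expanded below
)

MUSCLE_BANDS = (("dorsal", 5), ("medial", 5), ("ventral", 2))

#: Per-motor-pair neuromuscular defaults: pair label -> (junction count for
#: the pair, fraction of junctions onto left-side muscle).
DEFAULT_NMJ_PAIRS: dict[str, tuple[int, float]] = {
    "MN1": (599, 0.40),
    "MN2": (482, 0.46),
    "MN3": (70, 0.60),
    "MN4": (75, 0.60),
    "MN5": (36, 0.58),
}


def truncated_geometric_mean(p: float, kmax: int) -> float:
    """Exact mean of a geometric(p) distribution truncated to 1..kmax."""
    q = 1.0 - p
    norm = 1.0 - q**kmax
    return sum(k * p * q ** (k - 1) for k in range(1, kmax + 1)) / norm


def _sample_truncated_geometric(rng: np.random.Generator, p: float, kmax: int, size: int) -> np.ndarray:
    u = rng.random(size)
    q = 1.0 - p
    # inverse CDF of the truncated geometric
    k = np.floor(np.log1p(-u * (1.0 - q**kmax)) / np.log(q)) + 1
    return np.clip(k.astype(int), 1, kmax)


def _negbin_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var <= mean:
        raise ValueError(f"negative binomial needs SD^2 > mean (got mean={mean}, sd={sd})")
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return r, p


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated-world parameters of the synthetic connectome."""

    roster_spec: tuple[tuple[str, str, str, int], ...] = DEFAULT_ROSTER_SPEC
    presyn_mean: float = 49.0
    presyn_sd: float = 61.0
    gap_mean: float = 13.0
    gap_sd: float = 23.0
    chem_span: tuple[float, int] = (2.0 / 7.0, 29)  # geometric p, cap -> mean 3.5
    nmj_span: tuple[float, int] = (0.2, 65)  # mean ~5 sections
    gap_span: tuple[float, int] = (1.0 / 1.8, 55)  # mean 1.8
    polyad_p: float = 0.107
    dyad_share: float = 0.93
    reciprocity_target: float = 0.39
    unpolarized_p: float = 0.052
    dcv_p: float = 0.08
    power_a: float = 4.5
    power_b: float = 0.8
    nmj_pairs: tuple[tuple[str, tuple[int, float]], ...] = tuple(DEFAULT_NMJ_PAIRS.items())
    bm_rate: float = 0.03  # extra contacts onto the basal lamina, per chemical contact
    ep_rate: float = 0.005  # onto ependymal cells
    space_rate: float = 0.005  # onto no apparent postsynaptic partner
    thickness_zones: tuple[tuple[int, int, float], ...] = (
        (0, 3374, 60.0),
        (3375, 4734, 70.0),
        (4735, 6927, 100.0),
    )
    seed: int = 0

    def validated(self) -> "GeneratorConfig":
        for name in ("polyad_p", "dyad_share", "reciprocity_target", "unpolarized_p", "dcv_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability")
        for name in ("chem_span", "nmj_span", "gap_span"):
            p, cap = getattr(self, name)
            if not 0.0 < p < 1.0 or cap < 1:
                raise ValueError(f"{name}=({p}, {cap}) is infeasible")
        if self.power_b <= 0 or self.power_a <= 0:
            raise ValueError("power coupling parameters must be positive")
        for _, (n, share) in self.nmj_pairs:
            if n < 0 or not 0.0 <= share <= 1.0:
                raise ValueError("infeasible NMJ pair configuration")
        return self


_SIDE_TAG = {"left": "L", "right": "R", "midline": "M", "unassigned": "U"}
MIDLINE_X = 100.0


def build_roster(spec=DEFAULT_ROSTER_SPEC, rng: np.random.Generator | None = None) -> list[CellRecord]:
    """Expand a roster spec into cells with side-consistent nucleus positions.

    Nucleus x-positions are placed strictly left of (40..90 px), on (100 px),
    or right of (110..160 px) the midline at x=100 so that side assignment
    from nucleus geometry round-trips the declared side.
    """
    rng = rng or np.random.default_rng(0)
    cells: list[CellRecord] = []
    counters: dict[tuple[str, str], int] = {}
    for cell_type, region, side, count in spec:
        if cell_type == "muscle":
            continue
        for _ in range(count):
            key = (cell_type, side)
            counters[key] = counters.get(key, 0) + 1
            tag = _SIDE_TAG[side]
            base = cell_type.replace(" ", "")
            cid = f"{base}_{tag}{counters[key]}" if cell_type != "MN" else f"MN{counters[key]}_{tag}"
            if cell_type == "MGIN":
                cid = f"MGIN{counters[key]}_{tag}"
            if side == "left":
                x = float(rng.uniform(40, 90))
            elif side == "right":
                x = float(rng.uniform(110, 160))
            else:
                x = MIDLINE_X
            section = int(rng.integers(0, 3300))
            cells.append(
                CellRecord(
                    cell_id=cid,
                    cell_type=cell_type,
                    region=region,
                    side=side,
                    nucleus_position=(section, x, float(rng.uniform(20, 80))),
                    is_neuron=True,
                    has_cilium=bool(rng.random() < 0.7),
                )
            )
    # muscle cells in dorsal/medial/ventral bands on each side
    for side in ("left", "right"):
        tag = _SIDE_TAG[side]
        for band, n in MUSCLE_BANDS:
            for i in range(1, n + 1):
                x = float(rng.uniform(40, 90)) if side == "left" else float(rng.uniform(110, 160))
                cells.append(
                    CellRecord(
                        cell_id=f"mus-{band}_{tag}{i}",
                        cell_type="muscle",
                        region="muscle",
                        side=side,
                        nucleus_position=(int(rng.integers(3300, 4700)), x, 50.0),
                        is_neuron=False,
                    )
                )
    # postsynaptic-only pseudo-cells and ependymal cells
    cells.append(CellRecord("basal-lamina", "basal-lamina", "other", "midline", None, False))
    cells.append(CellRecord("space", "space", "other", "unassigned", None, False))
    for i in range(1, 5):
        cells.append(
            CellRecord(f"ependymal_{i}", "ependymal", "BV", "midline", (i, MIDLINE_X, 50.0), False)
        )
    return cells


def generate(config: GeneratorConfig | None = None) -> Connectome:
    """Generate one synthetic connectome from the stated-world config."""
    cfg = (config or GeneratorConfig()).validated()
    rng = np.random.default_rng(cfg.seed)
    cells = build_roster(cfg.roster_spec, rng)
    roster = {c.cell_id: c for c in cells}
    neurons = [c.cell_id for c in cells if c.is_neuron]
    cns = [c.cell_id for c in cells if c.is_neuron and c.region in ("BV", "neck", "MG", "CNC")]
    schedule = ThicknessSchedule(cfg.thickness_zones)
    contacts: list[ContactRecord] = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:06d}"

    chem_p, chem_cap = cfg.chem_span
    pre_comp_choices = np.array(["axon", "terminal", "soma", "dendrite"])
    pre_comp_probs = np.array([0.45, 0.35, 0.15, 0.05])
    # post compartments: axon+terminal together carry ~68% of synapses
    post_comp_choices = np.array(["axon", "terminal", "soma", "dendrite"])
    post_comp_probs = np.array([0.43, 0.25, 0.20, 0.12])

    # neuron -> set of existing postsynaptic neuron partners; polyad extras for
    # contacts created after the scaffold are drawn from here so that they
    # never create new neuron pairs (keeping the reciprocity calibration exact)
    out_partners: dict[str, set[str]] = {}

    def polyad_targets(pre: str, primary: str, mode: str) -> tuple[str, ...]:
        if rng.random() >= cfg.polyad_p:
            return (primary,)
        n_extra = 1 if rng.random() < cfg.dyad_share else 2
        if mode == "random":
            others = neuron_arr[(neuron_arr != pre) & (neuron_arr != primary)]
            extras = [str(t) for t in rng.choice(others, size=n_extra, replace=False)]
        else:  # existing partners only
            candidates = sorted(out_partners.get(pre, set()) - {primary, pre})
            if not candidates:
                return (primary,)
            n_extra = min(n_extra, len(candidates))
            extras = [str(t) for t in rng.choice(candidates, size=n_extra, replace=False)]
        return (primary, *extras)

    def make_chemical(pre: str, targets: tuple[str, ...], span: int) -> ContactRecord:
        for t in targets:
            if roster[t].is_neuron:
                out_partners.setdefault(pre, set()).add(t)
        first = int(rng.integers(0, 3374 - span + 1))
        vesicles = {"small-lucent"}
        if rng.random() < cfg.dcv_p:
            vesicles.add(str(rng.choice(["dcv-small", "dcv-medium", "dcv-large"])))
        return ContactRecord(
            contact_id=next_id("syn"),
            kind=CHEMICAL,
            pre_cell=pre,
            post_targets=targets,
            first_section=first,
            n_sections=span,
            thickness_nm_per_section=None,
            unpolarized=bool(rng.random() < cfg.unpolarized_p),
            vesicle_classes=frozenset(vesicles),
            pre_compartment=str(rng.choice(pre_comp_choices, p=pre_comp_probs)),
            post_compartments=tuple(
                str(rng.choice(post_comp_choices, p=post_comp_probs)) for _ in targets
            ),
        )

    # --- neuron-to-neuron chemical synapses --------------------------------
    r_nb, p_nb = _negbin_params(cfg.presyn_mean, cfg.presyn_sd)
    neuron_arr = np.array(cns)
    for pre in cns:
        s_i = max(1, int(rng.negative_binomial(r_nb, p_nb)))
        pool = neuron_arr[neuron_arr != pre]
        p_i = int(round((s_i / cfg.power_a) ** (1.0 / cfg.power_b)))
        p_i = min(max(p_i, 1), min(s_i, len(pool)))
        partners = rng.choice(pool, size=p_i, replace=False)
        # every partner gets one contact; the rest are spread uniformly
        alloc = np.ones(p_i, dtype=int)
        extra = rng.integers(0, p_i, size=s_i - p_i)
        np.add.at(alloc, extra, 1)
        spans = _sample_truncated_geometric(rng, chem_p, chem_cap, s_i)
        k = 0
        for j, partner in enumerate(partners):
            for _ in range(alloc[j]):
                contacts.append(
                    make_chemical(pre, polyad_targets(pre, str(partner), "random"), int(spans[k]))
                )
                k += 1

    # --- synapses onto basal lamina / ependymal / space --------------------
    # polyad extras here come from existing partners only, so these contacts
    # never create new neuron pairs
    n_chem = len(contacts)
    ep_ids = [c.cell_id for c in cells if c.cell_type == "ependymal"]
    for rate, target_of in (
        (cfg.bm_rate, lambda: "basal-lamina"),
        (cfg.ep_rate, lambda: str(rng.choice(ep_ids))),
        (cfg.space_rate, lambda: "space"),
    ):
        n = int(round(rate * n_chem))
        pres = rng.choice(neuron_arr, size=n) if n else []
        spans = _sample_truncated_geometric(rng, chem_p, chem_cap, n)
        for pre, span in zip(pres, spans):
            contacts.append(
                make_chemical(str(pre), polyad_targets(str(pre), target_of(), "partners"), int(span))
            )

    # --- reciprocity: post-hoc mirroring with analytic probability ---------
    # runs after every other neuron-pair-creating step so the mirroring
    # probability q is exact in expectation for the final pair population
    directed: set[tuple[str, str]] = set()
    for c in contacts:
        for t in c.post_targets:
            if t != c.pre_cell and roster[t].is_neuron:
                directed.add((c.pre_cell, t))
    pairs: dict[tuple[str, str], int] = {}
    for a, b in directed:
        key = (a, b) if a <= b else (b, a)
        pairs[key] = pairs.get(key, 0) + 1
    r0 = sum(1 for v in pairs.values() if v == 2)
    u0 = len(pairs) - r0
    if u0 > 0:
        q = (cfg.reciprocity_target * len(pairs) - r0) / u0
        q = min(max(q, 0.0), 1.0)
        one_way = sorted((a, b) for (a, b) in directed if (b, a) not in directed)
        flips = rng.random(len(one_way)) < q
        spans = _sample_truncated_geometric(rng, chem_p, chem_cap, len(one_way))
        for (a, b), flip, span in zip(one_way, flips, spans):
            if flip:
                contacts.append(
                    make_chemical(b, polyad_targets(b, a, "partners"), int(span))
                )

    # --- neuromuscular junctions ------------------------------------------
    nmj_p, nmj_cap = cfg.nmj_span
    muscle_by_side_band: dict[tuple[str, str], list[str]] = {}
    for c in cells:
        if c.cell_type == "muscle":
            band = c.cell_id.split("-", 1)[1].split("_")[0]
            muscle_by_side_band.setdefault((c.side, band), []).append(c.cell_id)
    for pair_label, (n_junctions, left_share) in cfg.nmj_pairs:
        members = [cid for cid in roster if cid.startswith(pair_label + "_")]
        if not members:
            continue
        sides = np.where(rng.random(n_junctions) < left_share, "left", "right")
        spans = _sample_truncated_geometric(rng, nmj_p, nmj_cap, n_junctions)
        for side, span in zip(sides, spans):
            band = "dorsal" if rng.random() < 0.7 else "medial"
            pool = muscle_by_side_band[(str(side), band)]
            target = str(rng.choice(pool))
            targets = [target]
            # polyadic NMJs hit additional muscle cells of the same side, so
            # dyad expansion never perturbs the configured left:right skew
            if rng.random() < cfg.polyad_p:
                n_extra = 1 if rng.random() < cfg.dyad_share else 2
                others = [m for m in pool if m != target]
                n_extra = min(n_extra, len(others))
                targets.extend(str(t) for t in rng.choice(others, size=n_extra, replace=False))
            pre = str(rng.choice(members))
            first = int(rng.integers(3200, 4734 - span + 1))
            contacts.append(
                ContactRecord(
                    contact_id=next_id("nmj"),
                    kind=CHEMICAL,
                    pre_cell=pre,
                    post_targets=tuple(targets),
                    first_section=first,
                    n_sections=int(span),
                    unpolarized=False,
                    vesicle_classes=frozenset({"small-lucent"}),
                    pre_compartment="terminal",
                    post_compartments=("muscle",) * len(targets),
                )
            )

    # --- gap junctions -----------------------------------------------------
    gap_p, gap_cap = cfg.gap_span
    r_g, p_g = _negbin_params(cfg.gap_mean, cfg.gap_sd)
    for cid in cns:
        n_g = int(rng.negative_binomial(r_g, p_g) // 2)  # each contact joins two cells
        if n_g == 0:
            continue
        pool = neuron_arr[neuron_arr != cid]
        partners = rng.choice(pool, size=n_g)
        spans = _sample_truncated_geometric(rng, gap_p, gap_cap, n_g)
        for partner, span in zip(partners, spans):
            first = int(rng.integers(0, 3374 - span + 1))
            contacts.append(
                ContactRecord(
                    contact_id=next_id("gap"),
                    kind=GAP,
                    pre_cell=cid,
                    post_targets=(str(partner),),
                    first_section=first,
                    n_sections=int(span),
                )
            )

    return Connectome.from_records(
        cells,
        contacts,
        schedule,
        provenance={"generator": "cionacns.synthetic.generate", "seed": cfg.seed},
    )


def scaling_population(
    n_neurons: int = 150,
    power_a: float = 4.5,
    power_b: float = 0.8,
    log_noise_sd: float = 0.3,
    depth_per_contact_um: float = 0.21,
    seed: int = 0,
):
    """Synthetic per-neuron scaling table: S = a * P^b with lognormal noise.

    Emulates the neuron-level population behind the synapse-count versus
    partner-count power law, without building a full connectome: partner
    counts P are drawn log-uniformly over 1..60, synapse counts are
    a * P^b * exp(eps) with eps ~ N(0, log_noise_sd^2), and total presynaptic
    depth is proportional to the synapse count with mild noise.  Returns a
    table shaped like :func:`cionacns.per_neuron_stats` output, for
    :func:`cionacns.fit_scaling` parameter-recovery checks.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    p_counts = np.exp(rng.uniform(0.0, np.log(60.0), n_neurons))
    p_counts = np.maximum(1, np.round(p_counts)).astype(int)
    eps = rng.normal(0.0, log_noise_sd, n_neurons)
    s_counts = np.maximum(1, np.round(power_a * p_counts**power_b * np.exp(eps))).astype(int)
    depth = s_counts * depth_per_contact_um * np.exp(rng.normal(0.0, 0.05, n_neurons))
    return pd.DataFrame(
        {
            "cell_type": "synthetic",
            "presyn_sites": s_counts,
            "presyn_sites_nonmuscle": s_counts,
            "received_synapses": 0,
            "gap_contacts": 0,
            "n_post_partners": p_counts,
            "n_pre_partners": 0,
            "total_depth_um": depth,
        },
        index=pd.Index([f"n{i:03d}" for i in range(n_neurons)], name="cell_id"),
    )


# --- deterministic fixtures -------------------------------------------------


def table1_marginal_connectome() -> Connectome:
    """Deterministic connectome whose contact totals equal the reference
    larva's printed marginals.

    Chemical: 8617 contacts spanning 30163 sections, of which 6618 span more
    than one section, 922 polyadic (858 dyads + 64 triads), 448 unpolarized,
    689 with dense-core vesicles.  Gap junctions: 3205 contacts spanning 5765
    sections, 1206 over one section.  All spans sit in the 60 nm zone.
    """
    cells = build_roster(rng=np.random.default_rng(12345))
    neurons = [c.cell_id for c in cells if c.is_neuron]
    n = len(neurons)
    contacts: list[ContactRecord] = []

    # spans: 1999 singles; 6618 multi-section (4926 of span 4, 1692 of span 5)
    spans = [1] * 1999 + [4] * 4926 + [5] * 1692
    assert len(spans) == 8617 and sum(spans) == 30163
    for i, span in enumerate(spans):
        pre = neurons[i % n]
        post1 = neurons[(i + 1) % n]
        targets = [post1]
        if 1999 <= i < 1999 + 858:  # dyads
            targets.append(neurons[(i + 2) % n])
        elif 1999 + 858 <= i < 1999 + 922:  # triads
            targets.extend([neurons[(i + 2) % n], neurons[(i + 3) % n]])
        contacts.append(
            ContactRecord(
                contact_id=f"syn{i:06d}",
                kind=CHEMICAL,
                pre_cell=pre,
                post_targets=tuple(targets),
                first_section=0,
                n_sections=span,
                unpolarized=i < 448,
                vesicle_classes=frozenset(
                    {"small-lucent", "dcv-small"} if i < 689 else {"small-lucent"}
                ),
            )
        )
    gap_spans = [1] * 1999 + [3] * 1058 + [4] * 148
    assert len(gap_spans) == 3205 and sum(gap_spans) == 5765
    for i, span in enumerate(gap_spans):
        contacts.append(
            ContactRecord(
                contact_id=f"gap{i:06d}",
                kind=GAP,
                pre_cell=neurons[i % n],
                post_targets=(neurons[(i + 5) % n],),
                first_section=0,
                n_sections=span,
            )
        )
    return Connectome.from_records(
        cells, contacts, provenance={"fixture": "table1-marginal (synthetic)"}
    )


def _simple_connectome(cells: list[CellRecord], edges: list[tuple[str, str, int]], tag: str) -> Connectome:
    contacts = [
        ContactRecord(f"{tag}{i:03d}", CHEMICAL, pre, (post,), 0, span)
        for i, (pre, post, span) in enumerate(edges)
    ]
    return Connectome.from_records(cells, contacts, provenance={"fixture": tag})


def _plain_cell(cid: str, side: str, region: str = "MG", cell_type: str = "MGIN") -> CellRecord:
    return CellRecord(cid, cell_type, region, side)


def mirror_fixture() -> tuple[Connectome, dict[str, str]]:
    """Perfectly mirror-symmetric paired network; side_diff must be empty."""
    pairs = {f"A{i}_L": f"A{i}_R" for i in (1, 2, 3)}
    cells = [_plain_cell(c, "left") for c in pairs] + [
        _plain_cell(c, "right") for c in pairs.values()
    ]
    edges = []
    for a, b, span in (("A1", "A2", 3), ("A2", "A3", 2), ("A1", "A3", 4)):
        edges.append((f"{a}_L", f"{b}_L", span))
        edges.append((f"{a}_R", f"{b}_R", span))
    return _simple_connectome(cells, edges, "mir"), pairs


def one_sided_fixture() -> tuple[Connectome, dict[str, str]]:
    """Mirror network plus one extra left-only edge (A3_L -> A1_L)."""
    conn, pairs = mirror_fixture()
    contacts = list(conn.contacts)
    contacts.append(ContactRecord("one000", CHEMICAL, "A3_L", ("A1_L",), 0, 2))
    return (
        Connectome.from_records(conn.cells.values(), contacts, provenance={"fixture": "one-sided"}),
        pairs,
    )


def layered_fixture() -> Connectome:
    """Layered sensory -> interneuron -> motor network; shortest arc = 2 synapses."""
    cells = [
        _plain_cell("PR_R1", "right", "BV", "PR-I"),
        _plain_cell("PR_R2", "right", "BV", "PR-I"),
        _plain_cell("RN_L1", "left", "BV", "prRN"),
        _plain_cell("RN_L2", "left", "BV", "prRN"),
        _plain_cell("MGIN1_L", "left", "MG", "MGIN"),
        _plain_cell("MN1_L", "left", "MG", "MN"),
        _plain_cell("MN1_R", "right", "MG", "MN"),
    ]
    edges = [
        ("PR_R1", "RN_L1", 3),
        ("PR_R1", "RN_L2", 2),
        ("PR_R2", "RN_L1", 4),
        ("RN_L1", "MGIN1_L", 5),
        ("RN_L2", "MGIN1_L", 2),
        ("RN_L1", "MN1_L", 2),  # the disynaptic shortcut
        ("MGIN1_L", "MN1_L", 6),
        ("MGIN1_L", "MN1_R", 3),
    ]
    return _simple_connectome(cells, edges, "lay")


def generate_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical fixtures as CSVs plus a manifest of expected values.

    The manifest values are recomputed here with independent plain-Python
    tallies (not the package's metric functions), so the fixtures double as
    cross-checks.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "note": "synthetic fixtures; contact spans and identities carry no inter-contact "
        "correlation structure (independence assumed)",
    }

    marginal = table1_marginal_connectome()
    cio.write_contacts(marginal, out / "marginal_contacts.csv")
    cio.write_roster(marginal, out / "marginal_roster.csv")
    chem = [c for c in marginal.contacts if c.kind == CHEMICAL]
    gap = [c for c in marginal.contacts if c.kind == GAP]
    manifest["marginal"] = {
        "chemical_total": len(chem),
        "chemical_sections": sum(c.n_sections for c in chem),
        "chemical_over_1_section": sum(1 for c in chem if c.n_sections > 1),
        "mean_sections_per_contact": sum(c.n_sections for c in chem) / len(chem),
        "gap_total": len(gap),
        "gap_sections": sum(c.n_sections for c in gap),
        "polyad_fraction": sum(1 for c in chem if len(c.post_targets) > 1) / len(chem),
    }

    mirror, pairs = mirror_fixture()
    cio.write_contacts(mirror, out / "mirror_contacts.csv")
    cio.write_roster(mirror, out / "mirror_roster.csv")
    left_edges = {(c.pre_cell, c.post_targets[0]) for c in mirror.contacts if c.pre_cell.endswith("_L")}
    right_edges = {
        (c.pre_cell.replace("_R", "_L"), c.post_targets[0].replace("_R", "_L"))
        for c in mirror.contacts
        if c.pre_cell.endswith("_R")
    }
    manifest["mirror"] = {
        "homolog_pairs": pairs,
        "n_left_only": len(left_edges - right_edges),
        "n_right_only": len(right_edges - left_edges),
    }

    one_sided, _ = one_sided_fixture()
    cio.write_contacts(one_sided, out / "one_sided_contacts.csv")

    layered = layered_fixture()
    cio.write_contacts(layered, out / "layered_contacts.csv")
    cio.write_roster(layered, out / "layered_roster.csv")
    # brute-force BFS for the expected minimum sensory->motor hop count
    adj: dict[str, set[str]] = {}
    for c in layered.contacts:
        adj.setdefault(c.pre_cell, set()).add(c.post_targets[0])
    best = None
    for s in ("PR_R1", "PR_R2"):
        frontier, dist = {s}, 0
        seen = {s}
        while frontier:
            dist += 1
            frontier = {t for f in frontier for t in adj.get(f, ()) if t not in seen}
            seen |= frontier
            if any(t.startswith("MN") for t in frontier):
                best = dist if best is None else min(best, dist)
                break
    manifest["layered"] = {"min_arc_synapses": best}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
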