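"""Synapse-level descriptive statistics.

Covers the headline contact counts (totals, section spans, unpolarized /
polyadic / dense-core-vesicle percentages for chemical synapses and gap
junctions), polyad arity distributions, the placement of contacts over cell
compartments, per-neuron synapse budgets, and the two empirical scaling laws
of the connectome: total contact depth grows linearly with a neuron's synapse
count, and synapse count grows as a power function of the number of
postsynaptic partners.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CHEMICAL,
    GAP,
    Connectome,
    _excluded_types,
    contact_depth,
    contact_is_excluded,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching printed-table rounding."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass
class KindSummary:
    """Contact totals and rates for one contact kind."""

    total_contacts: int
    total_sections: int
    contacts_over_1_section: int
    n_unpolarized: int = 0
    n_polyadic: int = 0
    n_dcv: int = 0

    @property
    def mean_sections_per_contact(self) -> float:
        return self.total_sections / self.total_contacts if self.total_contacts else float("nan")

    @property
    def mean_sections_over_1_section(self) -> float:
        multi = self.total_sections - (self.total_contacts - self.contacts_over_1_section)
        return multi / self.contacts_over_1_section if self.contacts_over_1_section else float("nan")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total_contacts if self.total_contacts else float("nan")

    @property
    def pct_unpolarized(self) -> float:
        return self._pct(self.n_unpolarized)

    @property
    def pct_polyadic(self) -> float:
        return self._pct(self.n_polyadic)

    @property
    def pct_dcv(self) -> float:
        return self._pct(self.n_dcv)

    def rounded(self) -> dict:
        """Printed-precision view: means to 1 decimal, percentages to 1 decimal."""
        return {
            "total_contacts": self.total_contacts,
            "total_sections": self.total_sections,
            "mean_sections_per_contact": round_half_up(self.mean_sections_per_contact),
            "contacts_over_1_section": self.contacts_over_1_section,
            "mean_sections_over_1_section": round_half_up(self.mean_sections_over_1_section),
            "pct_unpolarized": round_half_up(self.pct_unpolarized),
            "pct_polyadic": round_half_up(self.pct_polyadic),
            "pct_dcv": round_half_up(self.pct_dcv),
        }


@dataclass
class ContactSummary:
    chemical: KindSummary
    gap: KindSummary

    def to_dict(self) -> dict:
        return {"chemical": self.chemical.rounded(), "gap": self.gap.rounded()}


def summarize_contacts(
    connectome: Connectome,
    exclusions: tuple[str, ...] = (),
    min_sections: int = 1,
) -> ContactSummary:
    """Headline synapse and gap-junction statistics.

    A contact is dropped when its span is below ``min_sections`` or when every
    one of its postsynaptic targets is removed by ``exclusions``; a polyad
    that keeps at least one target still counts once.  Gap junctions have no
    polarity or polyad semantics, so their unpolarized/polyad/dcv percentages
    are reported but only the dcv one is anatomically meaningful.
    """
    excluded = _excluded_types(exclusions)
    out: dict[str, KindSummary] = {}
    for kind in (CHEMICAL, GAP):
        total = sections = over1 = unpol = poly = dcv = 0
        for c in connectome.contacts:
            if c.kind != kind or contact_is_excluded(connectome, c, excluded, min_sections):
                continue
            total += 1
            sections += c.n_sections
            if c.n_sections > 1:
                over1 += 1
            if c.unpolarized:
                unpol += 1
            if c.is_polyadic:
                poly += 1
            if c.has_dcv:
                dcv += 1
        out[kind] = KindSummary(total, sections, over1, unpol, poly, dcv)
    if out[CHEMICAL].total_contacts == 0 and out[GAP].total_contacts == 0:
        warnings.warn("no contacts survive the active filters; summary is all zeros")
    return ContactSummary(chemical=out[CHEMICAL], gap=out[GAP])


ARITY_NAMES = {1: "monad", 2: "dyad", 3: "triad", 4: "tetrad"}


@dataclass
class PolyadDistribution:
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_polyadic(self) -> int:
        return sum(n for a, n in self.counts.items() if a >= 2)

    @property
    def polyad_fraction(self) -> float:
        return self.n_polyadic / self.total if self.total else float("nan")

    @property
    def dyad_share(self) -> float | None:
        """Dyads as a fraction of all polyadic contacts; None when no polyads."""
        if self.n_polyadic == 0:
            return None
        return self.counts.get(2, 0) / self.n_polyadic

    def named_counts(self) -> dict[str, int]:
        return {ARITY_NAMES.get(a, f"{a}-ad"): n for a, n in sorted(self.counts.items())}


def polyad_distribution(connectome: Connectome) -> PolyadDistribution:
    """Arity distribution (monad/dyad/triad/...) of chemical contacts."""
    counts: dict[int, int] = {}
    for c in connectome.contacts_of_kind(CHEMICAL):
        counts[c.arity] = counts.get(c.arity, 0) + 1
    return PolyadDistribution(counts)


@dataclass
class CompartmentDistribution:
    #: fractions on the requested index: (pre, post) pairs or one marginal
    fractions: pd.Series
    n_annotated: int
    n_unknown: int
    #: always the full (pre, post) pair fractions, whatever ``direction`` was
    pair_fractions: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def post_fraction(self, compartments: set[str] | tuple[str, ...]) -> float:
        """Fraction of annotated pairs terminating on the given compartments."""
        comp = set(compartments)
        mask = [post in comp for (_pre, post) in self.pair_fractions.index]
        return float(self.pair_fractions[mask].sum())


def compartment_distribution(
    connectome: Connectome, direction: str = "pair"
) -> CompartmentDistribution:
    """Where chemical contacts sit on the pre- and postsynaptic cells.

    Counts one observation per postsynaptic target (so a dyad contributes
    two).  Pairs whose pre or post compartment is ``unknown`` are excluded
    from the fractions and reported separately.  ``direction`` selects the
    index: ``"pair"`` (pre x post), ``"pre"``, or ``"post"``.
    """
    tally: dict[tuple[str, str], int] = {}
    unknown = 0
    for c in connectome.contacts_of_kind(CHEMICAL):
        for rank in range(c.arity):
            post_comp = c.post_compartments[rank] if rank < len(c.post_compartments) else "unknown"
            if c.pre_compartment == "unknown" or post_comp == "unknown":
                unknown += 1
                continue
            key = (c.pre_compartment, post_comp)
            tally[key] = tally.get(key, 0) + 1
    n = sum(tally.values())
    frac = pd.Series(
        {k: v / n for k, v in sorted(tally.items())} if n else {}, dtype=float
    )
    pair_frac = frac.copy()
    if direction == "pre":
        frac = frac.groupby(lambda k: k[0]).sum() if n else frac
    elif direction == "post":
        frac = frac.groupby(lambda k: k[1]).sum() if n else frac
    elif direction != "pair":
        raise ValueError(f"unknown direction {direction!r}")
    return CompartmentDistribution(frac, n, unknown, pair_frac)


def per_neuron_stats(
    connectome: Connectome,
    include_types: tuple[str, ...] = (),
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-cell synapse budgets plus a population summary in ``.attrs``.

    One row per CNS neuron with at least one presynaptic site (the default
    denominator; pass ``include_types=("BTN",)`` to add the bipolar tail
    neurons).  Columns: presynaptic site count (and the count excluding
    neuromuscular junctions), received synapse count, gap-junction contact
    count, distinct post/pre partner counts over neurons, and total
    presynaptic depth in um.  The summary mean/SD uses population SD by
    default (``ddof=0``), configurable via ``ddof``.
    """
    pre_count: dict[str, int] = {}
    pre_nonmuscle: dict[str, int] = {}
    received: dict[str, int] = {}
    gap_count: dict[str, int] = {}
    post_partners: dict[str, set] = {}
    pre_partners: dict[str, set] = {}
    depth: dict[str, float] = {}
    cells = connectome.cells
    schedule = connectome.thickness_schedule
    for c in connectome.contacts:
        if c.kind == GAP:
            a, b = c.canonical_gap_pair()
            gap_count[a] = gap_count.get(a, 0) + 1
            gap_count[b] = gap_count.get(b, 0) + 1
            continue
        pre_count[c.pre_cell] = pre_count.get(c.pre_cell, 0) + 1
        d = contact_depth(c, schedule)
        depth[c.pre_cell] = depth.get(c.pre_cell, 0.0) + d
        onto_muscle = any(
            t in cells and cells[t].cell_type == "muscle" for t in c.post_targets
        )
        if not onto_muscle:
            pre_nonmuscle[c.pre_cell] = pre_nonmuscle.get(c.pre_cell, 0) + 1
        for t in c.post_targets:
            cell = cells.get(t)
            if cell is not None and cell.is_neuron:
                received[t] = received.get(t, 0) + 1
                post_partners.setdefault(c.pre_cell, set()).add(t)
                pre_partners.setdefault(t, set()).add(c.pre_cell)

    keep_regions = {"BV", "neck", "MG", "CNC"}
    rows = []
    for cid, cell in cells.items():
        if not cell.is_neuron:
            continue
        in_cns = cell.region in keep_regions
        if not in_cns and cell.cell_type not in include_types:
            continue
        n_pre = pre_count.get(cid, 0)
        if n_pre == 0:
            continue
        rows.append(
            {
                "cell_id": cid,
                "cell_type": cell.cell_type,
                "presyn_sites": n_pre,
                "presyn_sites_nonmuscle": pre_nonmuscle.get(cid, 0),
                "received_synapses": received.get(cid, 0),
                "gap_contacts": gap_count.get(cid, 0),
                "n_post_partners": len(post_partners.get(cid, ())),
                "n_pre_partners": len(pre_partners.get(cid, ())),
                "total_depth_um": depth.get(cid, 0.0),
            }
        )
    table = pd.DataFrame(rows).set_index("cell_id") if rows else pd.DataFrame(
        columns=[
            "cell_type",
            "presyn_sites",
            "presyn_sites_nonmuscle",
            "received_synapses",
            "gap_contacts",
            "n_post_partners",
            "n_pre_partners",
            "total_depth_um",
        ]
    )
    summary = {}
    for col in ("presyn_sites", "received_synapses", "gap_contacts"):
        if len(table):
            v = table[col].to_numpy(dtype=float)
            summary[col] = {
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=ddof)),
                "min": float(v.min()),
                "max": float(v.max()),
            }
    table.attrs["summary"] = summary
    table.attrs["n_neurons"] = len(table)
    return table


@dataclass
class ScalingFits:
    """Linear depth~count fit and power-law count~partners fit."""

    linear_slope: float
    linear_intercept: float
    linear_r2: float
    power_prefactor: float
    power_exponent: float
    power_r2: float
    n_rows_linear: int
    n_rows_power: int


def fit_scaling(
    per_neuron_table: pd.DataFrame,
    count_col: str = "presyn_sites_nonmuscle",
    partner_col: str = "n_post_partners",
    depth_col: str = "total_depth_um",
) -> ScalingFits:
    """Fit the two neuron-level scaling relations.

    * total presynaptic depth vs synapse count: ordinary least squares on the
      raw values, reported with r^2 (empirically near-linear, r^2 ~ 0.9);
    * synapse count S vs postsynaptic partner count P: power law S = a * P^b,
      fitted by least squares on log-log transformed values (r^2 on the log
      scale).  Rows with non-positive S or P are excluded with a warning.
    """
    t = per_neuron_table
    if len(t) < 3:
        raise ValueError("need at least 3 neurons to fit scaling relations")
    lin = stats.linregress(t[count_col].to_numpy(float), t[depth_col].to_numpy(float))
    s = t[count_col].to_numpy(float)
    p = t[partner_col].to_numpy(float)
    ok = (s > 0) & (p > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} neuron(s) with non-positive counts excluded from the power fit"
        )
    if ok.sum() < 3:
        raise ValueError("need at least 3 neurons with positive counts for the power fit")
    pw = stats.linregress(np.log(p[ok]), np.log(s[ok]))
    return ScalingFits(
        linear_slope=float(lin.slope),
        linear_intercept=float(lin.intercept),
        linear_r2=float(lin.rvalue**2),
        power_prefactor=float(np.exp(pw.intercept)),
        power_exponent=float(pw.slope),
        power_r2=float(pw.rvalue**2),
        n_rows_linear=len(t),
        n_rows_power=int(ok.sum()),
    )
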