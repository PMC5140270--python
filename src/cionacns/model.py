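"""Core data model for a serial-section EM connectome.

The model mirrors how annotated contact tables from serial-section electron
microscopy are organised: a roster of cells (neurons plus postsynaptic-only
pseudo-cells such as muscle and the basal lamina), a list of annotated
contacts (chemical synapses, neuromuscular junctions and putative gap
junctions), and a section-thickness schedule describing how thick each
ultrathin section was along the anterior-posterior axis.

The central derived quantity is the *cumulative depth* of a contact: the
number of serial sections a contact spans multiplied by the per-section
thickness, in micrometres.  Summed over all contacts of an ordered cell pair
it is the standard anatomical proxy for synaptic strength, and is the edge
weight used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

CHEMICAL = "chemical"
GAP = "gap"
KINDS = (CHEMICAL, GAP)

SIDES = ("left", "right", "midline", "unassigned")
REGIONS = ("BV", "neck", "MG", "CNC", "PNS", "muscle", "other")
COMPARTMENTS = (
    "soma",
    "axon",
    "terminal",
    "dendrite",
    "BVterm",
    "muscle",
    "basal-lamina",
    "unknown",
)

DCV_CLASSES = frozenset({"dcv-small", "dcv-medium", "dcv-large"})
VESICLE_CLASSES = frozenset({"small-lucent", "large-lucent"}) | DCV_CLASSES

#: Exclusion keyword -> cell type of the postsynaptic target being excluded.
#: ``bm`` drops synapses onto the basal lamina, ``Ep`` those onto ependymal
#: cells, ``Mu`` neuromuscular junctions, ``space`` synapses with no apparent
#: postsynaptic partner.
EXCLUSION_TYPES: Mapping[str, str] = {
    "bm": "basal-lamina",
    "Ep": "ependymal",
    "Mu": "muscle",
    "space": "space",
}

#: Section-thickness zones of the reference series: 3375 sections at 60 nm
#: (brain vesicle through motor ganglion), 1360 at 70 nm (anterior tail),
#: 2193 at 100 nm (remaining tail).  Zones are closed 0-based index ranges.
DEFAULT_THICKNESS_ZONES = ((0, 3374, 60.0), (3375, 4734, 70.0), (4735, 6927, 100.0))

EDGE_COLUMNS = ("pre", "post", "kind", "n_contacts", "total_sections", "cumulative_depth_um")


class SectionOutsideScheduleError(KeyError):
    """A contact spans a section index not covered by the thickness schedule."""


@dataclass(frozen=True)
class ThicknessSchedule:
    """Per-section nm thickness, as closed ``(start, end, thickness_nm)`` zones."""

    zones: tuple[tuple[int, int, float], ...] = DEFAULT_THICKNESS_ZONES

    def thickness(self, section: int) -> float:
        for start, end, t in self.zones:
            if start <= section <= end:
                return t
        raise SectionOutsideScheduleError(
            f"section {section} is outside the thickness schedule"
        )

    def covers(self, first_section: int, n_sections: int) -> bool:
        try:
            self.thickness(first_section)
            self.thickness(first_section + n_sections - 1)
        except SectionOutsideScheduleError:
            return False
        return True

    def profile(self, first_section: int, n_sections: int) -> tuple[float, ...]:
        """Per-section thicknesses of a span (may straddle zone boundaries)."""
        return tuple(
            self.thickness(s) for s in range(first_section, first_section + n_sections)
        )


@dataclass(frozen=True)
class CellRecord:
    """One cell of the roster: a neuron, or a postsynaptic-only pseudo-cell."""

    cell_id: str
    cell_type: str
    region: str = "other"
    side: str = "unassigned"
    #: (section index, x px, y px) of the nucleus, or None when not traced.
    nucleus_position: tuple[int, float, float] | None = None
    is_neuron: bool = True
    has_cilium: bool | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r} for cell {self.cell_id}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r} for cell {self.cell_id}")


@dataclass(frozen=True)
class ContactRecord:
    """One annotated synaptic or gap-junctional contact.

    ``post_targets`` is ordered; chemical contacts with two or more targets
    are polyadic (dyads, triads, ...).  Gap-junction contacts have exactly one
    partner and unordered semantics: they are canonicalised with the
    lexicographically smaller cell first.
    """

    contact_id: str
    kind: str
    pre_cell: str
    post_targets: tuple[str, ...]
    first_section: int
    n_sections: int
    #: Per-section thickness in nm; None means "resolve from the schedule".
    thickness_nm_per_section: tuple[float, ...] | None = None
    unpolarized: bool = False
    vesicle_classes: frozenset[str] = frozenset()
    pre_compartment: str = "unknown"
    post_compartments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        object.__setattr__(self, "post_targets", tuple(self.post_targets))
        if self.thickness_nm_per_section is not None:
            object.__setattr__(
                self, "thickness_nm_per_section", tuple(self.thickness_nm_per_section)
            )
        object.__setattr__(self, "vesicle_classes", frozenset(self.vesicle_classes))
        # pad/truncate to one compartment per postsynaptic target
        comps = tuple(self.post_compartments)[: len(self.post_targets)]
        comps += ("unknown",) * (len(self.post_targets) - len(comps))
        object.__setattr__(self, "post_compartments", comps)

    @property
    def arity(self) -> int:
        return len(self.post_targets)

    @property
    def is_polyadic(self) -> bool:
        return self.kind == CHEMICAL and self.arity >= 2

    @property
    def has_dcv(self) -> bool:
        return bool(self.vesicle_classes & DCV_CLASSES)

    def canonical_gap_pair(self) -> tuple[str, str]:
        if self.kind != GAP:
            raise ValueError("canonical pair is defined for gap contacts only")
        a, b = self.pre_cell, self.post_targets[0]
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ValidationFinding:
    code: str
    message: str
    contact_id: str | None = None
    cell_id: str | None = None


@dataclass
class Connectome:
    """Validated container of cells, contacts and the thickness schedule."""

    cells: dict[str, CellRecord]
    contacts: list[ContactRecord]
    thickness_schedule: ThicknessSchedule = field(default_factory=ThicknessSchedule)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        cells: Iterable[CellRecord],
        contacts: Iterable[ContactRecord],
        thickness_schedule: ThicknessSchedule | None = None,
        provenance: dict | None = None,
    ) -> "Connectome":
        roster: dict[str, CellRecord] = {}
        for c in cells:
            if c.cell_id in roster:
                raise ValueError(f"duplicate cell_id {c.cell_id!r}")
            roster[c.cell_id] = c
        return cls(
            cells=roster,
            contacts=list(contacts),
            thickness_schedule=thickness_schedule or ThicknessSchedule(),
            provenance=provenance or {},
        )

    def cell(self, cell_id: str) -> CellRecord:
        return self.cells[cell_id]

    def neurons(self) -> list[CellRecord]:
        return [c for c in self.cells.values() if c.is_neuron]

    def contacts_of_kind(self, kind: str) -> list[ContactRecord]:
        return [c for c in self.contacts if c.kind == kind]

    def with_sides(self, sides: Mapping[str, str]) -> "Connectome":
        """Return a copy with the given cells' sides replaced."""
        cells = {
            cid: (replace(cell, side=sides[cid]) if cid in sides else cell)
            for cid, cell in self.cells.items()
        }
        return Connectome(cells, list(self.contacts), self.thickness_schedule, dict(self.provenance))


def validate(connectome: Connectome) -> list[ValidationFinding]:
    """Structural validation; an empty report means the connectome is well formed.

    Reported findings: contacts referencing cells absent from the roster,
    zero-length section spans, polyadic gap contacts, spans outside the
    thickness schedule, and thickness profiles whose length disagrees with
    the section count.
    """
    findings: list[ValidationFinding] = []
    roster = connectome.cells
    seen_ids: set[str] = set()
    for c in connectome.contacts:
        if c.contact_id in seen_ids:
            findings.append(
                ValidationFinding("duplicate-contact-id", f"contact id {c.contact_id!r} repeated", c.contact_id)
            )
        seen_ids.add(c.contact_id)
        for cid in (c.pre_cell, *c.post_targets):
            if cid not in roster:
                findings.append(
                    ValidationFinding(
                        "dangling-reference",
                        f"contact {c.contact_id} references absent cell {cid!r}",
                        c.contact_id,
                        cid,
                    )
                )
        if c.n_sections < 1:
            findings.append(
                ValidationFinding("zero-length-span", f"contact {c.contact_id} spans {c.n_sections} sections", c.contact_id)
            )
        if c.kind == GAP and c.arity != 1:
            findings.append(
                ValidationFinding("polyadic-gap", f"gap contact {c.contact_id} has {c.arity} partners", c.contact_id)
            )
        if c.thickness_nm_per_section is not None and len(c.thickness_nm_per_section) != c.n_sections:
            findings.append(
                ValidationFinding(
                    "thickness-mismatch",
                    f"contact {c.contact_id}: {len(c.thickness_nm_per_section)} thickness values for {c.n_sections} sections",
                    c.contact_id,
                )
            )
        elif c.thickness_nm_per_section is None and c.n_sections >= 1:
            if not connectome.thickness_schedule.covers(c.first_section, c.n_sections):
                findings.append(
                    ValidationFinding(
                        "outside-schedule",
                        f"contact {c.contact_id} spans sections outside the thickness schedule",
                        c.contact_id,
                    )
                )
    return findings


MidlineGeometry = float | Mapping[int, float] | Callable[[int], float]


def assign_side(
    cell: CellRecord,
    midline: MidlineGeometry,
    nucleus_radius: float = 0.0,
) -> str:
    """Classify a cell as left / right / midline from its nucleus position.

    The midline is the x-coordinate of a dorso-ventral line through the neural
    canal, given per section (mapping or callable) or as a single constant.
    Nuclei whose centre lies within ``nucleus_radius`` pixels of the line are
    classified as midline; cells without a traced nucleus are ``unassigned``.

    The convention is that smaller x is the animal's left.
    """
    if cell.nucleus_position is None:
        return "unassigned"
    section, x, _y = cell.nucleus_position
    if callable(midline):
        mid = float(midline(section))
    elif isinstance(midline, Mapping):
        mid = float(midline[section])
    else:
        mid = float(midline)
    if abs(x - mid) <= nucleus_radius:
        return "midline"
    return "left" if x < mid else "right"


def contact_depth(contact: ContactRecord, schedule: ThicknessSchedule | None = None) -> float:
    """Cumulative depth of one contact in micrometres.

    Sums per-section thickness over the spanned sections (so contacts that
    straddle a 60/70 or 70/100 nm zone boundary are exact) and converts
    nm -> um.
    """
    if contact.n_sections < 1:
        raise ValueError(f"contact {contact.contact_id} has no sections")
    if contact.thickness_nm_per_section is not None:
        if len(contact.thickness_nm_per_section) != contact.n_sections:
            raise ValueError(
                f"contact {contact.contact_id}: thickness profile length "
                f"{len(contact.thickness_nm_per_section)} != n_sections {contact.n_sections}"
            )
        total_nm = sum(contact.thickness_nm_per_section)
    else:
        if schedule is None:
            raise ValueError(
                f"contact {contact.contact_id} has no thickness profile and no schedule was given"
            )
        total_nm = sum(schedule.profile(contact.first_section, contact.n_sections))
    return total_nm / 1000.0


def _excluded_types(exclusions: Iterable[str]) -> set[str]:
    excluded = set()
    for key in exclusions:
        if key not in EXCLUSION_TYPES:
            raise ValueError(
                f"unknown exclusion keyword {key!r}; known: {sorted(EXCLUSION_TYPES)}"
            )
        excluded.add(EXCLUSION_TYPES[key])
    return excluded


def contact_is_excluded(
    connectome: Connectome, contact: ContactRecord, excluded_types: set[str], min_sections: int
) -> bool:
    """True when a whole contact is dropped by the active filters."""
    if contact.n_sections < min_sections:
        return True
    if not excluded_types:
        return False
    kept = [
        t
        for t in contact.post_targets
        if connectome.cells.get(t) is None
        or connectome.cells[t].cell_type not in excluded_types
    ]
    return not kept


def build_edge_table(
    connectome: Connectome,
    kind: str = CHEMICAL,
    exclusions: Iterable[str] = (),
    min_sections: int = 1,
    unpolarized: str = "annotated",
) -> pd.DataFrame:
    """Aggregate contacts into a weighted edge table, one row per ordered pair.

    Each polyadic contact contributes its full section span and depth to
    *every* surviving postsynaptic target.  ``exclusions`` drops individual
    postsynaptic targets by pseudo-cell type (keywords ``bm``, ``Ep``, ``Mu``,
    ``space``); ``min_sections`` drops whole contacts spanning fewer sections.
    Gap-junction rows use the canonical unordered pair (lexicographically
    smaller cell first).

    ``unpolarized`` is ``"annotated"`` (store the annotated direction only,
    the default) or ``"mirror"`` (additionally emit the reversed direction for
    contacts flagged unpolarized).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    if unpolarized not in ("annotated", "mirror"):
        raise ValueError(f"unknown unpolarized mode {unpolarized!r}")
    excluded = _excluded_types(exclusions)
    schedule = connectome.thickness_schedule
    acc: dict[tuple[str, str], list] = {}

    def add(pre: str, post: str, secs: int, depth: float) -> None:
        row = acc.setdefault((pre, post), [0, 0, 0.0])
        row[0] += 1
        row[1] += secs
        row[2] += depth

    for c in connectome.contacts:
        if c.kind != kind or c.n_sections < min_sections:
            continue
        depth = contact_depth(c, schedule)
        if kind == GAP:
            a, b = c.canonical_gap_pair()
            add(a, b, c.n_sections, depth)
            continue
        for t in c.post_targets:
            cell = connectome.cells.get(t)
            if cell is not None and cell.cell_type in excluded:
                continue
            add(c.pre_cell, t, c.n_sections, depth)
            if unpolarized == "mirror" and c.unpolarized:
                add(t, c.pre_cell, c.n_sections, depth)

    rows = [
        (pre, post, kind, n, secs, depth)
        for (pre, post), (n, secs, depth) in sorted(acc.items())
    ]
    table = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    table.attrs["kind"] = kind
    return table


def select_cells(
    connectome_or_roster,
    cell_type: str | Sequence[str] | None = None,
    region: str | Sequence[str] | None = None,
    side: str | Sequence[str] | None = None,
    is_neuron: bool | None = None,
) -> list[str]:
    """Cell ids matching the given attribute filters, in roster order."""
    cells = (
        connectome_or_roster.cells.values()
        if isinstance(connectome_or_roster, Connectome)
        else connectome_or_roster
    )

    def as_set(v):
        if v is None:
            return None
        return {v} if isinstance(v, str) else set(v)

    types, regions, sides = as_set(cell_type), as_set(region), as_set(side)
    out = []
    for c in cells:
        if types is not None and c.cell_type not in types:
            continue
        if regions is not None and c.region not in regions:
            continue
        if sides is not None and c.side not in sides:
            continue
        if is_neuron is not None and c.is_neuron != is_neuron:
            continue
        out.append(c.cell_id)
    return out


def total_edge_depth(edge_table: pd.DataFrame) -> float:
    return float(edge_table["cumulative_depth_um"].sum()) if len(edge_table) else 0.0
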