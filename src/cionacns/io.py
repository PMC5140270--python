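"""Readers and writers for the file shapes the pipeline touches.

All tabular interchange is plain CSV with fixed column orders and fixed
float formatting, so identical inputs always produce byte-identical files.  Connectivity matrices are square CSV tables of
cumulative depths in micrometres (rows = presynaptic cell, columns =
postsynaptic cell); graphs can additionally be exported as GraphML for
external viewers.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from .model import (
    CHEMICAL,
    EDGE_COLUMNS,
    GAP,
    CellRecord,
    Connectome,
    ContactRecord,
    ThicknessSchedule,
)

CONTACT_HEADER = [
    "contact_id",
    "kind",
    "pre_cell",
    "post_cell",
    "post_rank",
    "first_section",
    "n_sections",
    "thickness_profile",
    "unpolarized",
    "vesicle_classes",
    "pre_compartment",
    "post_compartment",
]

ROSTER_HEADER = [
    "cell_id",
    "cell_type",
    "region",
    "side",
    "nucleus_section",
    "nucleus_x",
    "nucleus_y",
    "is_neuron",
    "has_cilium",
]


class ContactFileError(ValueError):
    """Malformed contact table; carries (line number, message) pairs."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in problems[:20])
        super().__init__(f"{len(problems)} malformed row(s): {detail}")


def _fmt(x: float) -> str:
    """Deterministic float formatting; 12 significant digits keep matrix
    round trips within 1e-9 um, integers print without a dot."""
    if x == int(x):
        return str(int(x))
    return format(x, ".12g")


def _thickness_field(contact: ContactRecord) -> str:
    prof = contact.thickness_nm_per_section
    if prof is None:
        return ""
    if len(set(prof)) == 1:
        return _fmt(prof[0])
    return ";".join(_fmt(t) for t in prof)


def write_contacts(connectome: Connectome, path: str | Path) -> None:
    """Write the contact table, one row per postsynaptic target of a polyad."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CONTACT_HEADER)
        for c in connectome.contacts:
            for rank, post in enumerate(c.post_targets):
                post_comp = (
                    c.post_compartments[rank] if rank < len(c.post_compartments) else "unknown"
                )
                w.writerow(
                    [
                        c.contact_id,
                        c.kind,
                        c.pre_cell,
                        post,
                        rank,
                        c.first_section,
                        c.n_sections,
                        _thickness_field(c),
                        int(c.unpolarized),
                        ";".join(sorted(c.vesicle_classes)),
                        c.pre_compartment,
                        post_comp,
                    ]
                )


def _parse_thickness(field: str, n_sections: int) -> tuple[float, ...] | None:
    if not field:
        return None
    parts = [float(p) for p in field.split(";")]
    if len(parts) == 1:
        return tuple(parts * n_sections)
    return tuple(parts)


def read_contacts(
    path: str | Path,
    cells: Iterable[CellRecord] = (),
    thickness_schedule: ThicknessSchedule | None = None,
) -> Connectome:
    """Read a contact table; polyad rows sharing a contact_id are reassembled.

    Malformed rows (missing columns, non-positive section spans, inconsistent
    polyad ranks) raise :class:`ContactFileError` naming the 1-based line
    numbers.  ``cells`` may seed the roster; referenced cells missing from it
    are *not* invented, so ``validate`` can report dangling references.
    """
    problems: list[tuple[int, str]] = []
    groups: dict[str, list[tuple[int, dict]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or any(
            col not in reader.fieldnames for col in CONTACT_HEADER
        ):
            missing = [c for c in CONTACT_HEADER if c not in (reader.fieldnames or [])]
            raise ContactFileError([(1, f"missing mandatory column(s): {missing}")])
        for lineno, row in enumerate(reader, start=2):
            try:
                row["post_rank"] = int(row["post_rank"])
                row["first_section"] = int(row["first_section"])
                row["n_sections"] = int(row["n_sections"])
            except (TypeError, ValueError):
                problems.append((lineno, "non-integer rank/section field"))
                continue
            if row["n_sections"] < 1:
                problems.append((lineno, f"n_sections={row['n_sections']} (must be >=1)"))
                continue
            groups.setdefault(row["contact_id"], []).append((lineno, row))

    contacts: list[ContactRecord] = []
    for cid, rows in groups.items():
        rows.sort(key=lambda r: r[1]["post_rank"])
        ranks = [r[1]["post_rank"] for r in rows]
        if ranks != list(range(len(rows))):
            problems.append((rows[0][0], f"contact {cid!r}: post ranks {ranks} are not 0..{len(rows)-1}"))
            continue
        lineno, first = rows[0]
        try:
            thickness = _parse_thickness(first["thickness_profile"], first["n_sections"])
        except ValueError:
            problems.append((lineno, "unparseable thickness profile"))
            continue
        vc = frozenset(v for v in first["vesicle_classes"].split(";") if v)
        contacts.append(
            ContactRecord(
                contact_id=cid,
                kind=first["kind"],
                pre_cell=first["pre_cell"],
                post_targets=tuple(r[1]["post_cell"] for r in rows),
                first_section=first["first_section"],
                n_sections=first["n_sections"],
                thickness_nm_per_section=thickness,
                unpolarized=bool(int(first["unpolarized"] or 0)),
                vesicle_classes=vc,
                pre_compartment=first["pre_compartment"] or "unknown",
                post_compartments=tuple(r[1]["post_compartment"] or "unknown" for r in rows),
            )
        )
    if problems:
        raise ContactFileError(sorted(problems))
    return Connectome.from_records(cells, contacts, thickness_schedule)


def write_roster(connectome_or_cells, path: str | Path) -> None:
    cells = (
        connectome_or_cells.cells.values()
        if isinstance(connectome_or_cells, Connectome)
        else connectome_or_cells
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(ROSTER_HEADER)
        for c in cells:
            ns, nx_, ny = ("", "", "")
            if c.nucleus_position is not None:
                ns, nx_, ny = c.nucleus_position
                nx_, ny = _fmt(nx_), _fmt(ny)
            cil = "" if c.has_cilium is None else int(c.has_cilium)
            w.writerow([c.cell_id, c.cell_type, c.region, c.side, ns, nx_, ny, int(c.is_neuron), cil])


def read_roster(path: str | Path) -> list[CellRecord]:
    cells: list[CellRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ROSTER_HEADER if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"roster file missing mandatory column(s): {missing}")
        for row in reader:
            nucleus = None
            if row["nucleus_section"]:
                nucleus = (int(row["nucleus_section"]), float(row["nucleus_x"]), float(row["nucleus_y"]))
            cells.append(
                CellRecord(
                    cell_id=row["cell_id"],
                    cell_type=row["cell_type"],
                    region=row["region"],
                    side=row["side"],
                    nucleus_position=nucleus,
                    is_neuron=bool(int(row["is_neuron"])),
                    has_cilium=None if row["has_cilium"] == "" else bool(int(row["has_cilium"])),
                )
            )
    return cells


def write_thickness_schedule(schedule: ThicknessSchedule, path: str | Path) -> None:
    data = [
        {"start_section": s, "end_section": e, "thickness_nm": t}
        for s, e, t in schedule.zones
    ]
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(data, fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_thickness_schedule(path: str | Path) -> ThicknessSchedule:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    zones = tuple(
        (int(z["start_section"]), int(z["end_section"]), float(z["thickness_nm"]))
        for z in data
    )
    return ThicknessSchedule(zones)


# -- connectivity matrices ---------------------------------------------------



def _matrix_labels(ids: list[str], roster: Mapping[str, CellRecord] | None) -> list[str]:
    if roster is None:
        return list(ids)
    return [f"{i}|{roster[i].cell_type}" if i in roster else i for i in ids]


def _strip_label(label: str) -> str:
    return label.split("|", 1)[0]


def edge_table_to_matrix(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord] | None = None,
    pool_muscle: bool = False,
) -> pd.DataFrame:
    """Square depth matrix (um) from an edge table.

    With ``pool_muscle`` the dorsal and medial muscle-band cells are summed
    into single ``muscle-L`` / ``muscle-R`` columns per side, mirroring how
    muscle targets are presented in whole-brain connectivity matrices (the
    bands are electrically coupled by gap junctions and act together).
    """
    table = edge_table
    if pool_muscle:
        if roster is None:
            raise ValueError("pool_muscle requires a roster to find muscle cells")
        pooled = {}
        for cid, cell in roster.items():
            if cell.cell_type == "muscle" and cell.side in ("left", "right"):
                pooled[cid] = "muscle-L" if cell.side == "left" else "muscle-R"
        table = edge_table.copy()
        table["post"] = table["post"].map(lambda c: pooled.get(c, c))
        table["pre"] = table["pre"].map(lambda c: pooled.get(c, c))
        table = (
            table.groupby(["pre", "post", "kind"], as_index=False)[
                ["n_contacts", "total_sections", "cumulative_depth_um"]
            ].sum()
        )
    ids = sorted(set(table["pre"]) | set(table["post"]))
    if roster is not None:
        order = {cid: i for i, cid in enumerate(roster)}
        ids.sort(key=lambda c: (order.get(c, len(order)), c))
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for pre, post, depth in table[["pre", "post", "cumulative_depth_um"]].itertuples(index=False):
        mat.loc[pre, post] += depth
    labels = _matrix_labels(ids, roster)
    mat.index = labels
    mat.columns = labels
    return mat


def write_matrix(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord] | None,
    path: str | Path,
    pool_muscle: bool = False,
) -> None:
    mat = edge_table_to_matrix(edge_table, roster, pool_muscle)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["", *mat.columns])
        for label, row in mat.iterrows():
            w.writerow([label, *(_fmt(v) for v in row)])


def read_matrix(path: str | Path, kind: str = CHEMICAL) -> pd.DataFrame:
    """Edge table from a square depth matrix; zero entries produce no rows.

    Only cumulative depth is recoverable from a matrix, so ``n_contacts`` and
    ``total_sections`` are reported as missing (pd.NA).
    """
    raw = pd.read_csv(path, index_col=0)
    if raw.shape[0] != raw.shape[1]:
        raise ValueError(f"matrix is not square: {raw.shape[0]} rows x {raw.shape[1]} columns")
    rows_ = [_strip_label(str(i)) for i in raw.index]
    cols_ = [_strip_label(str(c)) for c in raw.columns]
    if len(set(rows_)) != len(rows_) or len(set(cols_)) != len(cols_):
        raise ValueError("matrix has duplicate row or column labels")
    if sorted(rows_) != sorted(cols_):
        raise ValueError("matrix row and column labels differ")
    rows = []
    for i, pre in enumerate(rows_):
        for j, post in enumerate(cols_):
            v = float(raw.iat[i, j])
            if v != 0.0:
                rows.append((pre, post, kind, pd.NA, pd.NA, v))
    table = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    table.attrs["kind"] = kind
    return table


def export_graphml(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord] | None,
    path: str | Path,
) -> None:
    """GraphML export for external viewers (directed for chemical synapse
    tables, undirected for gap-junction tables).

    Node attributes: cell_type, region, side.  Edge attributes: kind,
    n_contacts, total_sections, cumulative_depth_um.
    """
    kind = edge_table.attrs.get("kind", CHEMICAL)
    g = nx.Graph() if kind == GAP else nx.DiGraph()
    for row in edge_table.itertuples(index=False):
        g.add_edge(
            row.pre,
            row.post,
            kind=row.kind,
            n_contacts=0 if pd.isna(row.n_contacts) else int(row.n_contacts),
            total_sections=0 if pd.isna(row.total_sections) else int(row.total_sections),
            cumulative_depth_um=float(row.cumulative_depth_um),
        )
    if roster is not None:
        for node in g.nodes:
            if node in roster:
                cell = roster[node]
                g.nodes[node]["cell_type"] = cell.cell_type
                g.nodes[node]["region"] = cell.region
                g.nodes[node]["side"] = cell.side
    nx.write_graphml(g, path)
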