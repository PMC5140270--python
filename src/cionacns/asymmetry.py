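"""Left/right asymmetry quantification.

Covers sided cell censuses, neuromuscular left:right input ratios per motor
neuron pair, the laterality of relay-neuron projections into the motor
ganglion, side-sorted connectivity matrices, and edge-by-edge comparison of
homologous left/right subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import CHEMICAL, CellRecord, Connectome

SIDE_ORDER = ("left", "midline", "right", "unassigned")


def largest_remainder_percentages(counts: Sequence[float]) -> list[int]:
    """Integer percentages summing to exactly 100 (largest-remainder method)."""
    total = float(sum(counts))
    if total <= 0:
        raise ValueError("cannot compute percentages of a zero total")
    raw = [100.0 * c / total for c in counts]
    floors = [int(r) for r in raw]
    deficit = 100 - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - floors[i], reverse=True)
    for i in order[:deficit]:
        floors[i] += 1
    return floors


def sided_counts(
    roster: Mapping[str, CellRecord] | Iterable[CellRecord],
    by: str = "cell_type",
    neurons_only: bool = True,
) -> pd.DataFrame:
    """Cell census per (group x side), with region and overall margins.

    Rows are groups (cell types by default, or regions with ``by="region"``),
    columns left/midline/right/unassigned plus a total.  ``.attrs["totals"]``
    carries the per-region and all-CNS marginal counts.
    """
    cells = list(roster.values() if isinstance(roster, Mapping) else roster)
    if neurons_only:
        cells = [c for c in cells if c.is_neuron]
    groups: dict[str, dict[str, int]] = {}
    for c in cells:
        key = getattr(c, by)
        row = groups.setdefault(key, {s: 0 for s in SIDE_ORDER})
        row[c.side] += 1
    table = pd.DataFrame.from_dict(groups, orient="index").fillna(0).astype(int)
    table = table.reindex(columns=list(SIDE_ORDER))
    table["total"] = table.sum(axis=1)
    table = table.sort_index()

    cns_regions = {"BV", "neck", "MG", "CNC"}
    totals: dict[str, dict[str, int]] = {}
    for region in sorted({c.region for c in cells}):
        members = [c for c in cells if c.region == region]
        totals[region] = {s: sum(1 for c in members if c.side == s) for s in SIDE_ORDER}
    cns = [c for c in cells if c.region in cns_regions]
    totals["all_CNS"] = {s: sum(1 for c in cns if c.side == s) for s in SIDE_ORDER}
    table.attrs["totals"] = totals
    return table


@dataclass
class LRRatio:
    """Left:right neuromuscular input of one motor-neuron pair."""

    group: str
    left_count: int
    right_count: int
    left_sections: int
    right_sections: int

    @property
    def ratio_by_count(self) -> tuple[int, int]:
        l, r = largest_remainder_percentages([self.left_count, self.right_count])
        return l, r

    @property
    def ratio_by_sections(self) -> tuple[int, int]:
        l, r = largest_remainder_percentages([self.left_sections, self.right_sections])
        return l, r

    def to_dict(self) -> dict:
        bc, bs = self.ratio_by_count, self.ratio_by_sections
        return {
            "group": self.group,
            "left_count": self.left_count,
            "right_count": self.right_count,
            "left_sections": self.left_sections,
            "right_sections": self.right_sections,
            "ratio_by_count": f"{bc[0]}:{bc[1]}",
            "ratio_by_sections": f"{bs[0]}:{bs[1]}",
        }


def nmj_lr_ratio(
    connectome: Connectome,
    motor_neuron_pair: str | Sequence[str],
    bands: tuple[str, ...] = ("dorsal", "medial"),
) -> LRRatio:
    """Left:right split of one motor-neuron pair's neuromuscular output.

    ``motor_neuron_pair`` is either an explicit sequence of motor-neuron cell
    ids or a label prefix (e.g. ``"MN2"``) matching cell ids like ``MN2_L`` /
    ``MN2_R``.  Junction counts and summed section counts are pooled over the
    dorsal and medial muscle bands of each side (the bands are electrically
    coupled and act as one unit); the muscle side is the target muscle cell's
    own side attribute.  Ratios print as integer percentage pairs that sum to
    100 (largest-remainder rounding).
    """
    if isinstance(motor_neuron_pair, str):
        pre_ids = {
            cid
            for cid in connectome.cells
            if cid == motor_neuron_pair or cid.startswith(motor_neuron_pair + "_")
        }
        label = motor_neuron_pair
    else:
        pre_ids = set(motor_neuron_pair)
        label = "+".join(sorted(pre_ids))
    if not pre_ids:
        raise ValueError(f"no cells match motor neuron pair {motor_neuron_pair!r}")

    def band_of(cell: CellRecord) -> str | None:
        # muscle cell ids carry their band, e.g. "mus-dorsal_L3"
        for b in ("dorsal", "medial", "ventral"):
            if b in cell.cell_id or b in cell.cell_type:
                return b
        return None

    counts = {"left": 0, "right": 0}
    sections = {"left": 0, "right": 0}
    for c in connectome.contacts_of_kind(CHEMICAL):
        if c.pre_cell not in pre_ids:
            continue
        for t in c.post_targets:
            cell = connectome.cells.get(t)
            if cell is None or cell.cell_type != "muscle":
                continue
            band = band_of(cell)
            if band is not None and band not in bands:
                continue
            if cell.side not in counts:
                continue
            counts[cell.side] += 1
            sections[cell.side] += c.n_sections
    if counts["left"] + counts["right"] == 0:
        raise ValueError(f"motor neuron pair {label!r} has no neuromuscular junctions")
    return LRRatio(label, counts["left"], counts["right"], sections["left"], sections["right"])


def relay_laterality(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord],
    source_class: str | Sequence[str],
    target_region: str = "MG",
    target_neurons_only: bool = True,
) -> dict:
    """Left vs right share of one relay class's output into a target region.

    Returns percentages of the class's synaptic output landing on left-side
    vs right-side targets of ``target_region``, both by contact count and by
    cumulative depth.  Midline targets are tallied separately and excluded
    from the L:R percentages.
    """
    classes = {source_class} if isinstance(source_class, str) else set(source_class)
    sources = {cid for cid, c in roster.items() if c.cell_type in classes}
    if not sources:
        raise ValueError(f"no roster cells of class {source_class!r}")
    count = {"left": 0.0, "right": 0.0, "midline": 0.0}
    depth = {"left": 0.0, "right": 0.0, "midline": 0.0}
    hit = False
    for row in edge_table.itertuples(index=False):
        if row.pre not in sources:
            continue
        cell = roster.get(row.post)
        if cell is None or cell.region != target_region:
            continue
        if target_neurons_only and not cell.is_neuron:
            continue
        if cell.side not in count:
            continue
        hit = True
        n = 0 if pd.isna(row.n_contacts) else float(row.n_contacts)
        count[cell.side] += n
        depth[cell.side] += float(row.cumulative_depth_um)
    if not hit:
        raise ValueError(
            f"class {source_class!r} has no outgoing edges into region {target_region!r}"
        )
    out = {"source_class": source_class, "target_region": target_region}
    for name, tally in (("by_count", count), ("by_depth", depth)):
        lr = tally["left"] + tally["right"]
        if lr > 0:
            out[name] = {
                "left_pct": 100.0 * tally["left"] / lr,
                "right_pct": 100.0 * tally["right"] / lr,
                "midline": tally["midline"],
            }
        else:
            out[name] = {"left_pct": float("nan"), "right_pct": float("nan"), "midline": tally["midline"]}
    return out


def sort_matrix_by_side(
    matrix: pd.DataFrame, roster: Mapping[str, CellRecord]
) -> tuple[pd.DataFrame, dict]:
    """Permute a connectivity matrix into left/right quadrants.

    Rows are ordered left, midline, right; columns right, midline, left — so
    the quadrants read, in order: left-to-right, left-to-left, right-to-left,
    right-to-right, with midline cells separating them.  Within each block
    the original (rostro-caudal) order is preserved.  Pooled-muscle and other
    sideless non-neuron labels are moved to trailing rows/columns; a sideless
    *neuron* label is an error.  Returns the permuted matrix and the quadrant
    index ranges.
    """

    def side_of(label: str) -> str:
        cid = label.split("|", 1)[0]
        if cid in roster:
            cell = roster[cid]
            if cell.side in ("left", "right", "midline"):
                return cell.side
            if not cell.is_neuron:
                return "other"
            return "missing"
        if cid.endswith("-L"):
            return "left"
        if cid.endswith("-R"):
            return "right"
        return "other"

    sides = {lab: side_of(lab) for lab in matrix.index}
    missing = sorted(lab for lab, s in sides.items() if s == "missing")
    if missing:
        raise ValueError(f"labels without an assigned side: {missing}")
    row_blocks = {"left": [], "midline": [], "right": [], "other": []}
    for lab in matrix.index:
        row_blocks[sides[lab]].append(lab)
    row_order = row_blocks["left"] + row_blocks["midline"] + row_blocks["right"] + row_blocks["other"]
    col_order = row_blocks["right"] + row_blocks["midline"] + row_blocks["left"] + row_blocks["other"]
    sorted_mat = matrix.loc[row_order, col_order]

    nl, nm, nr = (len(row_blocks[s]) for s in ("left", "midline", "right"))
    quadrants = {
        "rows": {"left": (0, nl), "midline": (nl, nl + nm), "right": (nl + nm, nl + nm + nr)},
        "cols": {"right": (0, nr), "midline": (nr, nr + nm), "left": (nr + nm, nr + nm + nl)},
        "quadrant_order": ["left->right", "left->left", "right->left", "right->right"],
    }
    return sorted_mat, quadrants


@dataclass
class SideDiffReport:
    """Edge-by-edge comparison of homologous left/right subnetworks.

    Edges are keyed by (left-side pre, left-side post) identity; right-side
    edges are mapped through the homolog pairing before comparison.  The
    three groups partition all edges among the paired cells.
    """

    both_sides: pd.DataFrame  # pre, post, left_depth, right_depth, weight_ratio
    left_only: pd.DataFrame  # pre, post, depth
    right_only: pd.DataFrame


def side_diff(
    edge_table: pd.DataFrame, homolog_pairs: Mapping[str, str]
) -> SideDiffReport:
    """Classify edges among homologous cells as both-sides / left-only / right-only.

    ``homolog_pairs`` maps each left-side cell id to its right-side homolog
    and must be a bijection.  Only edges with both endpoints inside the paired
    set are considered.  For both-sides edges the weight ratio is
    left depth / right depth.
    """
    left = list(homolog_pairs.keys())
    right = list(homolog_pairs.values())
    if len(set(left)) != len(left) or len(set(right)) != len(right):
        raise ValueError("homolog mapping is not a bijection")
    if set(left) & set(right):
        raise ValueError("homolog mapping has cells on both sides")
    to_left = {r: l for l, r in homolog_pairs.items()}
    left_set, right_set = set(left), set(right)

    left_edges: dict[tuple[str, str], float] = {}
    right_edges: dict[tuple[str, str], float] = {}
    for pre, post, depth in edge_table[["pre", "post", "cumulative_depth_um"]].itertuples(
        index=False
    ):
        if pre in left_set and post in left_set:
            left_edges[(pre, post)] = left_edges.get((pre, post), 0.0) + float(depth)
        elif pre in right_set and post in right_set:
            key = (to_left[pre], to_left[post])
            right_edges[key] = right_edges.get(key, 0.0) + float(depth)

    both, lonly, ronly = [], [], []
    for key in sorted(set(left_edges) | set(right_edges)):
        dl, dr = left_edges.get(key), right_edges.get(key)
        if dl is not None and dr is not None:
            both.append({"pre": key[0], "post": key[1], "left_depth_um": dl, "right_depth_um": dr, "weight_ratio": dl / dr})
        elif dl is not None:
            lonly.append({"pre": key[0], "post": key[1], "depth_um": dl})
        else:
            ronly.append({"pre": key[0], "post": key[1], "depth_um": dr})
    cols_b = ["pre", "post", "left_depth_um", "right_depth_um", "weight_ratio"]
    cols_s = ["pre", "post", "depth_um"]
    return SideDiffReport(
        both_sides=pd.DataFrame(both, columns=cols_b),
        left_only=pd.DataFrame(lonly, columns=cols_s),
        right_only=pd.DataFrame(ronly, columns=cols_s),
    )
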