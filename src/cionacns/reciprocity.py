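"""Pairwise reciprocity of chemical connections.

A pair of neurons is reciprocal when each is presynaptic to the other.  Two
pair-level measures are used: the *extent* of reciprocity, the cumulative
depth in the dominant direction divided by the summed depth in both
directions (1.0 for a one-way pair, 0.5 for a perfectly balanced reciprocal
pair), and the *geometric mean* of the two directed depths (defined only for
reciprocal pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .model import CellRecord


def _directed_depths(
    edge_table: pd.DataFrame, nodes: set[str] | None
) -> dict[tuple[str, str], float]:
    depths: dict[tuple[str, str], float] = {}
    for pre, post, depth in edge_table[["pre", "post", "cumulative_depth_um"]].itertuples(
        index=False
    ):
        if pre == post:
            continue  # self-loops carry no pair semantics
        if nodes is not None and (pre not in nodes or post not in nodes):
            continue
        depths[(pre, post)] = depths.get((pre, post), 0.0) + float(depth)
    return depths


def _neuron_set(roster) -> set[str] | None:
    if roster is None:
        return None
    cells = roster.values() if isinstance(roster, Mapping) else roster
    return {c.cell_id for c in cells if c.is_neuron}


def reciprocity_proportion(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord] | Iterable[CellRecord] | None = None,
) -> float:
    """Fraction of connected unordered neuron pairs with edges in both directions.

    The denominator is every unordered pair joined by at least one directed
    edge.  When a roster is given, pairs involving non-neurons (muscle, basal
    lamina, ependymal pseudo-cells — which can never be presynaptic and hence
    never reciprocal) are excluded.  Self-loops are ignored.
    """
    nodes = _neuron_set(roster)
    depths = _directed_depths(edge_table, nodes)
    if not depths:
        raise ValueError("edge table has no pair edges within the selected nodes")
    pairs: set[tuple[str, str]] = set()
    reciprocal = 0
    for a, b in depths:
        pair = (a, b) if a <= b else (b, a)
        if pair in pairs:
            continue
        pairs.add(pair)
        if (b, a) in depths and (a, b) in depths:
            reciprocal += 1
    return reciprocal / len(pairs)


@dataclass(frozen=True)
class PairReciprocity:
    cell_a: str
    cell_b: str
    d_forward_um: float  # depth in the dominant direction
    d_backward_um: float
    extent: float
    geometric_mean_um: float | None
    reciprocal: bool


def pair_reciprocity_table(
    edge_table: pd.DataFrame,
    roster: Mapping[str, CellRecord] | Iterable[CellRecord] | None = None,
) -> pd.DataFrame:
    """One row per connected unordered pair, histogram-ready.

    The extent is computed from the larger direction by convention, so it
    lies in (0.5, 1.0] for reciprocal pairs and is exactly 1.0 for one-way
    pairs; the extents of the two directions of a reciprocal pair sum to 1.
    The geometric mean sqrt(d_fwd * d_bwd) is reported as NaN for one-way
    pairs.
    """
    nodes = _neuron_set(roster)
    depths = _directed_depths(edge_table, nodes)
    rows = []
    for a, b in sorted({(min(p), max(p)) for p in depths}):
        d_ab = depths.get((a, b), 0.0)
        d_ba = depths.get((b, a), 0.0)
        fwd, bwd = (d_ab, d_ba) if d_ab >= d_ba else (d_ba, d_ab)
        reciprocal = d_ab > 0 and d_ba > 0
        rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "d_forward_um": fwd,
                "d_backward_um": bwd,
                "extent": fwd / (fwd + bwd),
                "geometric_mean_um": math.sqrt(d_ab * d_ba) if reciprocal else float("nan"),
                "reciprocal": reciprocal,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_a",
            "cell_b",
            "d_forward_um",
            "d_backward_um",
            "extent",
            "geometric_mean_um",
            "reciprocal",
        ],
    )
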