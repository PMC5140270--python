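"""Left/right asymmetry: censuses, NMJ ratios, laterality, matrix sorting, diffs."""

import math

import numpy as np
import pandas as pd
import pytest

import cionacns as cc
from cionacns.asymmetry import largest_remainder_percentages
from cionacns.model import EDGE_COLUMNS


class TestSidedCounts:
    def test_toy_counts(self):
        roster = [
            cc.CellRecord("a", "BVIN", "BV", "left"),
            cc.CellRecord("b", "BVIN", "BV", "left"),
            cc.CellRecord("c", "BVIN", "BV", "right"),
            cc.CellRecord("d", "BVIN", "BV", "midline"),
        ]
        t = cc.sided_counts(roster)
        assert (t.loc["BVIN", "left"], t.loc["BVIN", "right"], t.loc["BVIN", "midline"]) == (2, 1, 1)

    def test_full_roster_reference_census(self):
        """The default roster reproduces the 88 left / 15 centre / 75 right census."""
        cells = cc.build_roster(rng=np.random.default_rng(0))
        t = cc.sided_counts(cells)
        totals = t.attrs["totals"]["all_CNS"]
        assert (totals["left"], totals["midline"], totals["right"]) == (88, 15, 75)
        assert t.attrs["totals"]["BV"]["left"] == 72
        assert t.attrs["totals"]["MG"]["right"] == 12

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        sides = ["left", "right", "midline", "unassigned"]
        types = ["BVIN", "MN", "prRN"]
        roster = [
            cc.CellRecord(f"c{i}", str(rng.choice(types)), "BV", str(rng.choice(sides)))
            for i in range(100)
        ]
        t = cc.sided_counts(roster)
        for ct in types:
            for s in sides:
                brute = sum(1 for c in roster if c.cell_type == ct and c.side == s)
                assert t.loc[ct, s] == brute


class TestLargestRemainder:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 1), [50, 50]), ((224, 258), [46, 54]), ((1583, 1636), [49, 51]),
         ((192 + 47, 230 + 130), [40, 60]), ((21, 15), [58, 42])],
    )
    def test_reference_ratio_pairs(self, counts, expected):
        assert largest_remainder_percentages(counts) == expected

    def test_always_sums_to_100(self):
        rng = np.random.default_rng(19)
        for _ in range(200):
            counts = rng.integers(0, 500, size=int(rng.integers(2, 5))) + 1
            assert sum(largest_remainder_percentages(counts.tolist())) == 100


class TestNmjLrRatio:
    def _nmj_connectome(self, left_n, right_n, left_span=2, right_span=2):
        cells = [
            cc.CellRecord("MN2_L", "MN", "MG", "left"),
            cc.CellRecord("MN2_R", "MN", "MG", "right"),
            cc.CellRecord("mus-dorsal_L1", "muscle", "muscle", "left", is_neuron=False),
            cc.CellRecord("mus-dorsal_R1", "muscle", "muscle", "right", is_neuron=False),
        ]
        contacts = []
        for i in range(left_n):
            contacts.append(
                cc.ContactRecord(f"l{i}", "chemical", "MN2_L", ("mus-dorsal_L1",), 0, left_span)
            )
        for i in range(right_n):
            contacts.append(
                cc.ContactRecord(f"r{i}", "chemical", "MN2_R", ("mus-dorsal_R1",), 0, right_span)
            )
        return cc.Connectome.from_records(cells, contacts)

    def test_equal_counts_give_fifty_fifty(self):
        assert cc.nmj_lr_ratio(self._nmj_connectome(7, 7), "MN2").ratio_by_count == (50, 50)

    def test_reference_mn2_ratios(self):
        """Counts 224:258 and sections 1583:1636 print as 46:54 and 49:51."""
        lr = cc.LRRatio("MN2", 224, 258, 1583, 1636)
        assert lr.ratio_by_count == (46, 54)
        assert lr.ratio_by_sections == (49, 51)
        measured = cc.nmj_lr_ratio(self._nmj_connectome(224, 258), "MN2")
        assert measured.ratio_by_count == (46, 54)

    def test_zero_nmj_pair_errors(self):
        conn = self._nmj_connectome(1, 1)
        with pytest.raises(ValueError, match="no cells match|no neuromuscular"):
            cc.nmj_lr_ratio(conn, "MN9")

    def test_random_allocation_matches_brute_force(self):
        rng = np.random.default_rng(29)
        left, right = int(rng.integers(10, 300)), int(rng.integers(10, 300))
        lr = cc.nmj_lr_ratio(self._nmj_connectome(left, right), "MN2")
        want_left = round(100 * left / (left + right))
        assert abs(lr.ratio_by_count[0] - want_left) <= 1  # rounding convention
        assert lr.left_count == left and lr.right_count == right

    def test_count_and_section_ratios_agree_for_equal_spans(self):
        lr = cc.nmj_lr_ratio(self._nmj_connectome(30, 70), "MN2")
        assert lr.ratio_by_count == lr.ratio_by_sections == (30, 70)


class TestRelayLaterality:
    def _edge_table(self, rows):
        return pd.DataFrame(
            [(a, b, "chemical", n, n * 2, d) for a, b, n, d in rows], columns=EDGE_COLUMNS
        )

    def _roster(self):
        return {
            "prRN_L1": cc.CellRecord("prRN_L1", "prRN", "BV", "left"),
            "prRN_L2": cc.CellRecord("prRN_L2", "prRN", "BV", "left"),
            "MGIN1_L": cc.CellRecord("MGIN1_L", "MGIN", "MG", "left"),
            "MGIN1_R": cc.CellRecord("MGIN1_R", "MGIN", "MG", "right"),
        }

    def test_all_left_is_100_0(self):
        t = self._edge_table([("prRN_L1", "MGIN1_L", 3, 0.6)])
        out = cc.relay_laterality(t, self._roster(), "prRN")
        assert out["by_depth"]["left_pct"] == 100.0
        assert out["by_count"]["right_pct"] == 0.0

    def test_seventy_thirty_split_by_depth(self):
        t = self._edge_table(
            [("prRN_L1", "MGIN1_L", 5, 0.7), ("prRN_L2", "MGIN1_R", 2, 0.3)]
        )
        out = cc.relay_laterality(t, self._roster(), "prRN")
        assert out["by_depth"]["left_pct"] == pytest.approx(70.0)

    def test_missing_class_errors(self):
        t = self._edge_table([("prRN_L1", "MGIN1_L", 1, 0.1)])
        with pytest.raises(ValueError, match="no outgoing|no roster"):
            cc.relay_laterality(t, self._roster(), "antRN")

    def test_random_targets_match_brute_force(self):
        rng = np.random.default_rng(37)
        roster = self._roster()
        rows = []
        for i, src in enumerate(("prRN_L1", "prRN_L2")):
            for tgt in ("MGIN1_L", "MGIN1_R"):
                rows.append((src, tgt, int(rng.integers(1, 9)), float(rng.uniform(0.1, 2))))
        out = cc.relay_laterality(self._edge_table(rows), roster, "prRN")
        left_d = sum(d for _, t, _, d in rows if t == "MGIN1_L")
        tot_d = sum(d for *_, d in rows)
        assert out["by_depth"]["left_pct"] == pytest.approx(100 * left_d / tot_d)


class TestSortMatrixBySide:
    def _matrix_and_roster(self):
        roster = {
            "L1": cc.CellRecord("L1", "BVIN", "BV", "left"),
            "L2": cc.CellRecord("L2", "BVIN", "BV", "left"),
            "M1": cc.CellRecord("M1", "BVIN", "BV", "midline"),
            "R1": cc.CellRecord("R1", "BVIN", "BV", "right"),
            "R2": cc.CellRecord("R2", "BVIN", "BV", "right"),
        }
        rng = np.random.default_rng(43)
        ids = list(roster)
        mat = pd.DataFrame(rng.uniform(0, 1, (5, 5)), index=ids, columns=ids)
        return mat, roster

    def test_block_order(self):
        mat, roster = self._matrix_and_roster()
        sorted_mat, quads = cc.sort_matrix_by_side(mat, roster)
        assert list(sorted_mat.index) == ["L1", "L2", "M1", "R1", "R2"]
        assert list(sorted_mat.columns) == ["R1", "R2", "M1", "L1", "L2"]
        assert quads["rows"]["left"] == (0, 2)
        assert quads["cols"]["right"] == (0, 2)
        assert quads["quadrant_order"][0] == "left->right"

    def test_grand_total_preserved(self):
        mat, roster = self._matrix_and_roster()
        sorted_mat, _ = cc.sort_matrix_by_side(mat, roster)
        assert math.isclose(sorted_mat.to_numpy().sum(), mat.to_numpy().sum())

    def test_idempotent_ordering(self):
        mat, roster = self._matrix_and_roster()
        once, _ = cc.sort_matrix_by_side(mat, roster)
        twice, _ = cc.sort_matrix_by_side(once, roster)
        assert list(once.index) == list(twice.index)
        assert list(once.columns) == list(twice.columns)

    def test_quadrant_sums_match_partition(self):
        mat, roster = self._matrix_and_roster()
        sorted_mat, quads = cc.sort_matrix_by_side(mat, roster)
        r0, r1 = quads["rows"]["left"]
        c0, c1 = quads["cols"]["right"]
        quad_sum = sorted_mat.iloc[r0:r1, c0:c1].to_numpy().sum()
        brute = sum(
            mat.loc[i, j]
            for i in mat.index
            for j in mat.columns
            if roster[i].side == "left" and roster[j].side == "right"
        )
        assert math.isclose(quad_sum, brute)

    def test_sideless_neuron_errors(self):
        mat, roster = self._matrix_and_roster()
        roster["L1"] = cc.CellRecord("L1", "BVIN", "BV", "unassigned")
        with pytest.raises(ValueError, match="L1"):
            cc.sort_matrix_by_side(mat, roster)


class TestSideDiff:
    def test_mirror_network_has_no_one_sided_edges(self):
        conn, pairs = cc.mirror_fixture()
        report = cc.side_diff(cc.build_edge_table(conn), pairs)
        assert len(report.left_only) == 0
        assert len(report.right_only) == 0
        assert len(report.both_sides) == 3
        assert (report.both_sides["weight_ratio"] == 1.0).all()

    def test_single_extra_left_edge(self):
        conn, pairs = cc.one_sided_fixture()
        report = cc.side_diff(cc.build_edge_table(conn), pairs)
        assert len(report.left_only) == 1
        assert (report.left_only.iloc[0]["pre"], report.left_only.iloc[0]["post"]) == ("A3_L", "A1_L")
        assert len(report.right_only) == 0

    def test_non_bijective_mapping_errors(self):
        conn, pairs = cc.mirror_fixture()
        bad = dict(pairs)
        bad["A9_L"] = bad["A1_L"]
        with pytest.raises(ValueError, match="bijection"):
            cc.side_diff(cc.build_edge_table(conn), bad)

    def test_random_paired_networks_match_set_comparison(self):
        rng = np.random.default_rng(47)
        pairs = {f"h{i}_L": f"h{i}_R" for i in range(6)}
        cells = [cc.CellRecord(c, "MGIN", "MG", "left") for c in pairs] + [
            cc.CellRecord(c, "MGIN", "MG", "right") for c in pairs.values()
        ]
        left_ids, right_ids = list(pairs), list(pairs.values())
        contacts = []
        left_set, right_set = set(), set()
        k = 0
        for ids, store, side in ((left_ids, left_set, "L"), (right_ids, right_set, "R")):
            for a in ids:
                for b in ids:
                    if a != b and rng.random() < 0.3:
                        contacts.append(cc.ContactRecord(f"c{k}", "chemical", a, (b,), 0, 2))
                        store.add((a.split("_")[0], b.split("_")[0]))
                        k += 1
        conn = cc.Connectome.from_records(cells, contacts)
        report = cc.side_diff(cc.build_edge_table(conn), pairs)
        assert len(report.both_sides) == len(left_set & right_set)
        assert len(report.left_only) == len(left_set - right_set)
        assert len(report.right_only) == len(right_set - left_set)
        total = len(report.both_sides) + len(report.left_only) + len(report.right_only)
        assert total == len(left_set | right_set)
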