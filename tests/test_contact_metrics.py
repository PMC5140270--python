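"""Synapse statistics: headline summary, polyads, compartments, scaling fits."""

import math

import numpy as np
import pytest

import cionacns as cc
from cionacns.contact_metrics import round_half_up
from cionacns.synthetic import scaling_population


def _chain_connectome(arities, kind="chemical", spans=None):
    """Contacts cycling over four neurons, with given post-target arities."""
    cells = [cc.CellRecord(f"n{i}", "BVIN", "BV", "left") for i in range(4)]
    ids = [c.cell_id for c in cells]
    contacts = []
    for i, arity in enumerate(arities):
        targets = tuple(ids[(i + 1 + j) % 4] for j in range(arity))
        span = spans[i] if spans else 1
        contacts.append(cc.ContactRecord(f"c{i}", kind, ids[i % 4], targets, 0, span))
    return cc.Connectome.from_records(cells, contacts)


class TestSummarizeContacts:
    def test_reference_marginals(self, marginal_connectome):
        """Totals 8617 contacts / 30163 sections give mean 3.5; gap 5765/3205 -> 1.8."""
        s = cc.summarize_contacts(marginal_connectome)
        assert s.chemical.total_contacts == 8617
        assert s.chemical.total_sections == 30163
        assert round_half_up(s.chemical.mean_sections_per_contact) == 3.5
        assert s.chemical.contacts_over_1_section == 6618
        assert round_half_up(s.chemical.mean_sections_over_1_section) == 4.3
        assert round_half_up(s.chemical.pct_polyadic) == 10.7
        assert round_half_up(s.chemical.pct_unpolarized) == 5.2
        assert round_half_up(s.chemical.pct_dcv) == 8.0
        assert s.gap.total_contacts == 3205
        assert s.gap.total_sections == 5765
        assert round_half_up(s.gap.mean_sections_per_contact) == 1.8
        assert s.gap.contacts_over_1_section == 1206
        assert round_half_up(s.gap.mean_sections_over_1_section) == 3.1

    def test_defining_ratios_hold_exactly(self, default_connectome):
        s = cc.summarize_contacts(default_connectome)
        for kind in (s.chemical, s.gap):
            assert math.isclose(
                kind.mean_sections_per_contact, kind.total_sections / kind.total_contacts
            )
            assert 0 <= kind.pct_polyadic <= 100

    def test_min_sections_never_increases_counts(self, default_connectome):
        s1 = cc.summarize_contacts(default_connectome)
        s2 = cc.summarize_contacts(default_connectome, min_sections=2)
        assert s2.chemical.total_contacts <= s1.chemical.total_contacts
        assert s2.chemical.n_polyadic <= s1.chemical.n_polyadic
        assert s2.gap.total_contacts <= s1.gap.total_contacts
        assert s2.chemical.total_contacts == s1.chemical.contacts_over_1_section

    def test_empty_connectome_warns_and_zeroes(self):
        cells = [cc.CellRecord("A", "BVIN", "BV", "left")]
        conn = cc.Connectome.from_records(cells, [])
        with pytest.warns(UserWarning, match="no contacts"):
            s = cc.summarize_contacts(conn)
        assert s.chemical.total_contacts == 0
        assert math.isnan(s.chemical.mean_sections_per_contact)


class TestPolyadDistribution:
    def test_monads_only_has_undefined_dyad_share(self):
        dist = cc.polyad_distribution(_chain_connectome([1] * 10))
        assert dist.polyad_fraction == 0.0
        assert dist.dyad_share is None

    def test_ninety_three_dyads_and_seven_triads(self):
        dist = cc.polyad_distribution(_chain_connectome([2] * 93 + [3] * 7))
        assert dist.dyad_share == pytest.approx(0.93)
        assert dist.named_counts() == {"dyad": 93, "triad": 7}

    def test_matches_brute_force_tally_on_random_arities(self):
        rng = np.random.default_rng(5)
        arities = rng.integers(1, 4, size=200).tolist()
        dist = cc.polyad_distribution(_chain_connectome(arities))
        assert dist.total == 200
        for a in (1, 2, 3):
            assert dist.counts.get(a, 0) == sum(1 for x in arities if x == a)
        n_poly = sum(1 for x in arities if x >= 2)
        assert dist.polyad_fraction == pytest.approx(n_poly / 200)
        assert dist.dyad_share == pytest.approx(arities.count(2) / n_poly)


class TestCompartmentDistribution:
    def _with_compartments(self, pairs):
        cells = [cc.CellRecord("A", "BVIN", "BV", "left"), cc.CellRecord("B", "BVIN", "BV", "left")]
        contacts = [
            cc.ContactRecord(
                f"c{i}", "chemical", "A", ("B",), 0, 1,
                pre_compartment=pre, post_compartments=(post,),
            )
            for i, (pre, post) in enumerate(pairs)
        ]
        return cc.Connectome.from_records(cells, contacts)

    def test_all_axo_axonal(self):
        dist = cc.compartment_distribution(self._with_compartments([("axon", "axon")] * 5))
        assert dist.fractions[("axon", "axon")] == 1.0

    def test_axon_terminal_targeting_fraction(self):
        # 68 of 100 synapses terminate on axons or terminals
        pairs = [("axon", "axon")] * 40 + [("axon", "terminal")] * 28 + [("axon", "soma")] * 32
        dist = cc.compartment_distribution(self._with_compartments(pairs))
        assert dist.post_fraction({"axon", "terminal"}) == pytest.approx(0.68)

    def test_fractions_sum_to_one_and_unknowns_reported(self):
        rng = np.random.default_rng(9)
        comps = ["axon", "terminal", "soma", "dendrite", "unknown"]
        pairs = [(comps[rng.integers(4)], comps[rng.integers(5)]) for _ in range(300)]
        dist = cc.compartment_distribution(self._with_compartments(pairs))
        assert dist.fractions.sum() == pytest.approx(1.0)
        assert dist.n_unknown == sum(1 for p in pairs if "unknown" in p)
        brute = {}
        for p in pairs:
            if "unknown" not in p:
                brute[p] = brute.get(p, 0) + 1
        for key, n in brute.items():
            assert dist.fractions[key] == pytest.approx(n / dist.n_annotated)

    def test_post_marginal(self):
        pairs = [("axon", "axon"), ("terminal", "axon"), ("axon", "soma"), ("soma", "soma")]
        dist = cc.compartment_distribution(self._with_compartments(pairs), direction="post")
        assert dist.fractions["axon"] == pytest.approx(0.5)
        assert dist.fractions["soma"] == pytest.approx(0.5)


class TestPerNeuronStats:
    def test_single_neuron_three_contacts(self):
        cells = [cc.CellRecord("A", "BVIN", "BV", "left"), cc.CellRecord("B", "BVIN", "BV", "left")]
        contacts = [cc.ContactRecord(f"c{i}", "chemical", "A", ("B",), 0, 1) for i in range(3)]
        conn = cc.Connectome.from_records(cells, contacts)
        table = cc.per_neuron_stats(conn)
        assert table.loc["A", "presyn_sites"] == 3
        # only neurons with >=1 presynaptic site are in the denominator
        assert list(table.index) == ["A"]
        assert table.attrs["summary"]["presyn_sites"] == {
            "mean": 3.0, "sd": 0.0, "min": 3.0, "max": 3.0,
        }

    def test_range_endpoints(self):
        cells = [
            cc.CellRecord("lo", "BVIN", "BV", "left"),
            cc.CellRecord("hi", "BVIN", "BV", "left"),
            cc.CellRecord("sink", "BVIN", "BV", "left"),
        ]
        contacts = [cc.ContactRecord("a", "chemical", "lo", ("sink",), 0, 1)]
        contacts += [
            cc.ContactRecord(f"b{i}", "chemical", "hi", ("sink",), 0, 1) for i in range(430)
        ]
        conn = cc.Connectome.from_records(cells, contacts)
        summary = cc.per_neuron_stats(conn).attrs["summary"]["presyn_sites"]
        assert (summary["min"], summary["max"]) == (1.0, 430.0)

    def test_mean_sd_match_two_pass_oracle(self, default_connectome):
        table = cc.per_neuron_stats(default_connectome)
        vals = table["presyn_sites"].tolist()
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        got = table.attrs["summary"]["presyn_sites"]
        assert got["mean"] == pytest.approx(mean)
        assert got["sd"] == pytest.approx(sd)

    def test_counts_match_brute_force(self, toy_connectome):
        table = cc.per_neuron_stats(toy_connectome)
        assert table.loc["A", "presyn_sites"] == 1
        assert table.loc["A", "received_synapses"] == 1
        assert table.loc["A", "gap_contacts"] == 1
        assert table.loc["A", "n_post_partners"] == 2
        assert table.loc["B", "n_pre_partners"] == 1


class TestFitScaling:
    def test_exact_line(self):
        table = scaling_population(20, seed=0)
        table["total_depth_um"] = 2.0 * table["presyn_sites"]
        fits = cc.fit_scaling(table)
        assert fits.linear_slope == pytest.approx(2.0)
        assert fits.linear_r2 == pytest.approx(1.0)

    def test_exact_power_law(self):
        import pandas as pd

        p = np.arange(1, 21)
        s = 3.0 * p**1.5
        table = pd.DataFrame(
            {
                "presyn_sites_nonmuscle": s,
                "n_post_partners": p,
                "total_depth_um": s * 0.2,
                "presyn_sites": s,
            },
            index=pd.Index([f"n{i}" for i in p], name="cell_id"),
        )
        fits = cc.fit_scaling(table)
        assert fits.power_exponent == pytest.approx(1.5)
        assert fits.power_prefactor == pytest.approx(3.0)
        assert fits.power_r2 == pytest.approx(1.0)

    def test_recovers_generating_exponent_with_noise(self):
        """b = 0.8 population with lognormal noise: recovery within +/-0.1 at n=150."""
        fits = cc.fit_scaling(scaling_population(150, power_b=0.8, seed=1))
        assert abs(fits.power_exponent - 0.8) <= 0.1

    def test_row_order_invariance(self):
        table = scaling_population(50, seed=2)
        a = cc.fit_scaling(table)
        b = cc.fit_scaling(table.iloc[::-1])
        assert a.power_exponent == pytest.approx(b.power_exponent)
        assert a.linear_slope == pytest.approx(b.linear_slope)

    def test_nonpositive_rows_excluded_with_warning(self):
        table = scaling_population(30, seed=3)
        table.iloc[0, table.columns.get_loc("n_post_partners")] = 0
        with pytest.warns(UserWarning, match="non-positive"):
            fits = cc.fit_scaling(table)
        assert fits.n_rows_power == 29
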