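import pytest

import cionacns as cc


@pytest.fixture(scope="session")
def default_connectome():
    """One synthetic connectome at stated-world defaults (seed 0)."""
    return cc.generate(cc.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def ten_connectomes():
    """Ten default-world connectomes (seeds 0..9) for pooled recovery checks."""
    return [cc.generate(cc.GeneratorConfig(seed=s)) for s in range(10)]


@pytest.fixture(scope="session")
def marginal_connectome():
    """Deterministic fixture with the reference larva's printed contact totals."""
    return cc.table1_marginal_connectome()


@pytest.fixture()
def toy_connectome():
    """Three neurons, two chemical contacts (one dyad), one gap junction."""
    cells = [
        cc.CellRecord("A", "BVIN", "BV", "left", (10, 50.0, 40.0)),
        cc.CellRecord("B", "BVIN", "BV", "right", (12, 150.0, 40.0)),
        cc.CellRecord("C", "MGIN", "MG", "midline", (20, 100.0, 40.0)),
    ]
    contacts = [
        cc.ContactRecord("s1", "chemical", "A", ("B", "C"), 0, 3,
                         post_compartments=("axon", "terminal"), pre_compartment="terminal"),
        cc.ContactRecord("s2", "chemical", "B", ("A",), 5, 1, pre_compartment="axon",
                         post_compartments=("axon",)),
        cc.ContactRecord("g1", "gap", "C", ("A",), 2, 2),
    ]
    return cc.Connectome.from_records(cells, contacts)
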