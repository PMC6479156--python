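"""Shared fixtures: small deterministic spatial/phylogenetic objects and two
session-scoped synthetic-landscape pipeline runs (unbiased and biased
sampling) reused by the slower integration tests."""

import numpy as np
import pandas as pd
import pytest

import oceub as ob


@pytest.fixture
def grid5():
    return ob.build_hexgrid((0.0, 0.0, 5.0, 5.0), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(records):
    """records: list of (species, lon, lat) tuples."""
    df = pd.DataFrame(records, columns=["species", "lon", "lat"])
    df["group"] = "other"
    df["valid_geo"] = True
    df["valid_taxon"] = True
    return ob.OccurrenceTable(df)


@pytest.fixture
def balanced_tree():
    return ob.set_unit_branch_lengths(ob.parse_newick("((A,B),(C,D));"))


def random_presence(rng, n_cells=10, n_species=8):
    """Random presence matrix guaranteed nonempty in every row and column."""
    while True:
        m = rng.random((n_cells, n_species)) < 0.35
        if m.any(axis=0).all() and m.any(axis=1).all():
            break
    return ob.PresenceMatrix(
        pd.DataFrame(m, index=range(n_cells), columns=[f"sp{j}" for j in range(n_species)])
    )


def random_tree(rng, labels):
    """Random binary tree over the given tip labels, unit branch lengths."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b})")
    return ob.set_unit_branch_lengths(ob.parse_newick(nodes[0] + ";"))


# ---------------------------------------------------------------------------
# Session-scoped pipeline runs (expensive; shared across integration tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def landscape_unbiased():
    """Full planted landscape, dense spatially uniform sampling."""
    truth = ob.simulate_landscape(ob.SimulationConfig(seed=1))
    table = ob.sample_occurrences(truth, n_records=20000, bias=0.0, seed=101)
    report = ob.end_to_end_recovery(truth, table, ob.PipelineSettings().reseed(8))
    return truth, table, report


@pytest.fixture(scope="session")
def landscape_biased():
    """Full planted landscape with accessibility-biased sampling."""
    truth = ob.simulate_landscape(ob.SimulationConfig(seed=1))
    table = ob.sample_occurrences(truth, n_records=20000, bias=2.0, seed=101)
    report = ob.end_to_end_recovery(truth, table, ob.PipelineSettings().reseed(8))
    return truth, table, report
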