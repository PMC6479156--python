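"""Newick I/O, unit branch lengths, MRP supertrees, and branch-based metrics,
each checked against independent brute-force oracles."""

import itertools

import dendropy
import numpy as np
import pytest

import oceub as ob
from conftest import random_tree
from oceub.phylo import _N, _edges, _fitch_score


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def test_parse_simple_tree():
    t = ob.parse_newick("(A,(B,C));")
    assert ob.tip_labels(t) == ["A", "B", "C"]
    clades = {frozenset(l.taxon.label for l in n.leaf_iter()) for n in t.preorder_node_iter() if not n.is_leaf()}
    assert frozenset({"B", "C"}) in clades


def test_duplicate_tip_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        ob.parse_newick("(A,(B,B));")


def test_malformed_newick_rejected():
    with pytest.raises(ValueError):
        ob.parse_newick("(A,(B,C);")


def test_roundtrip_preserves_bipartitions(tmp_path, rng):
    t = random_tree(rng, [f"t{i}" for i in range(20)])
    p = tmp_path / "t.nwk"
    ob.write_newick(t, p)
    t2 = ob.read_newick(p)
    assert ob.bipartitions(t) == ob.bipartitions(t2)
    assert ob.tip_labels(t) == ob.tip_labels(t2)


# ---------------------------------------------------------------------------
# unit branch lengths
# ---------------------------------------------------------------------------


def test_unit_branch_lengths():
    t = ob.parse_newick("(A:0.3,(B:2.1,C:0.7):1.4);")
    u = ob.set_unit_branch_lengths(t)
    lens = [e.length for e in u.preorder_edge_iter() if e.head_node is not u.seed_node]
    assert all(l == 1.0 for l in lens)
    assert ob.bipartitions(u) == ob.bipartitions(t)
    # total length equals edge count; idempotent
    et = ob.EdgeTable.from_tree(u)
    assert et.total_length == len(et.lengths)
    u2 = ob.set_unit_branch_lengths(u)
    assert ob.EdgeTable.from_tree(u2).total_length == et.total_length


# ---------------------------------------------------------------------------
# Faith PD / PhyloSor vs path-union / edge-set oracles
# ---------------------------------------------------------------------------


def _dendropy_edge_sets(tree):
    """Oracle: per tip, the set of edges (node ids) on its root path."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = set()
        node = leaf
        while node.parent_node is not None:
            path.add(id(node))
            node = node.parent_node
        paths[leaf.taxon.label] = path
    lengths = {
        id(n): (n.edge.length or 1.0) for n in tree.preorder_node_iter() if n.parent_node is not None
    }
    return paths, lengths


def test_faith_pd_trivial_cases(balanced_tree):
    assert ob.faith_pd(["A", "B", "C", "D"], balanced_tree) == 6.0  # all tips: total length
    assert ob.faith_pd(["A"], balanced_tree) == 2.0  # single tip: its depth


def test_faith_pd_matches_path_union_oracle(rng):
    t = random_tree(rng, [f"x{i}" for i in range(10)])
    paths, lengths = _dendropy_edge_sets(t)
    tips = list(paths)
    for _ in range(20):
        k = rng.integers(1, 10)
        sub = list(rng.choice(tips, size=k, replace=False))
        union = set().union(*(paths[s] for s in sub))
        expect = sum(lengths[e] for e in union)
        assert ob.faith_pd(sub, t) == pytest.approx(expect)


def test_faith_pd_monotone_in_species(rng):
    t = random_tree(rng, [f"x{i}" for i in range(10)])
    tips = ob.tip_labels(t)
    sub = []
    prev = 0.0
    for s in rng.permutation(tips):
        sub.append(s)
        pd_now = ob.faith_pd(sub, t)
        assert pd_now >= prev
        prev = pd_now


def test_faith_pd_empty_intersection_is_zero(balanced_tree):
    assert ob.faith_pd(["nope"], balanced_tree) == 0.0


def test_phylosor_identity_and_symmetry(rng):
    t = random_tree(rng, [f"x{i}" for i in range(10)])
    tips = ob.tip_labels(t)
    a = list(rng.choice(tips, 4, replace=False))
    b = list(rng.choice(tips, 5, replace=False))
    assert ob.phylosor(a, a, t) == pytest.approx(1.0)
    assert ob.phylosor(a, b, t) == pytest.approx(ob.phylosor(b, a, t))


def test_phylosor_star_tree_equals_sorensen():
    star = ob.set_unit_branch_lengths(ob.parse_newick("(A,B,C,D,E);"))
    a, b = {"A", "B", "C"}, {"B", "C", "D", "E"}
    sor = 2 * len(a & b) / (len(a) + len(b))
    assert ob.phylosor(a, b, star) == pytest.approx(sor)


def test_phylosor_matches_edge_set_oracle(rng):
    t = random_tree(rng, [f"x{i}" for i in range(10)])
    paths, lengths = _dendropy_edge_sets(t)
    tips = list(paths)
    for _ in range(20):
        a = list(rng.choice(tips, rng.integers(1, 8), replace=False))
        b = list(rng.choice(tips, rng.integers(1, 8), replace=False))
        ea = set().union(*(paths[s] for s in a))
        eb = set().union(*(paths[s] for s in b))
        shared = sum(lengths[e] for e in ea & eb)
        pd_a = sum(lengths[e] for e in ea)
        pd_b = sum(lengths[e] for e in eb)
        assert ob.phylosor(a, b, t) == pytest.approx(shared / (0.5 * (pd_a + pd_b)))


def test_phylosor_empty_assemblage_errors(balanced_tree):
    with pytest.raises(ValueError):
        ob.phylosor([], ["A"], balanced_tree)


# ---------------------------------------------------------------------------
# PWE
# ---------------------------------------------------------------------------


def test_pwe_single_cell_holds_total_length(grid5, balanced_tree):
    import pandas as pd

    P = ob.PresenceMatrix(pd.DataFrame(True, index=[3], columns=["A", "B", "C", "D"]))
    s = ob.pwe_surface(P, balanced_tree, grid5)
    assert s.values[3] == pytest.approx(6.0)


def test_pwe_matches_branch_range_oracle(grid5, balanced_tree):
    import pandas as pd

    # 3 cells x 4 tips fixture
    data = pd.DataFrame(
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]],
        index=[0, 1, 2],
        columns=["A", "B", "C", "D"],
    ).astype(bool)
    P = ob.PresenceMatrix(data)
    s = ob.pwe_surface(P, balanced_tree, grid5)
    # oracle: enumerate branches of ((A,B),(C,D)) with unit lengths
    paths, lengths = _dendropy_edge_sets(balanced_tree)
    cells = {0: {"A", "B"}, 1: {"B", "C"}, 2: {"C", "D"}}
    ranges = {}
    for c, spp in cells.items():
        for e in set().union(*(paths[s_] for s_ in spp)):
            ranges.setdefault(e, set()).add(c)
    for c, spp in cells.items():
        expect = sum(lengths[e] / len(ranges[e]) for e in set().union(*(paths[s_] for s_ in spp)))
        assert s.values[c] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# MRP encoding and supertree search
# ---------------------------------------------------------------------------


def test_mrp_single_tree():
    m = ob.mrp_encode([ob.parse_newick("(A,(B,C));")])
    assert m.taxa == ["A", "B", "C"]
    assert m.n_columns == 1
    assert m.data[:, 0].tolist() == [0, 1, 1]


def test_mrp_duplicate_trees_keep_duplicate_columns():
    t = "(A,(B,(C,D)));"
    m = ob.mrp_encode([ob.parse_newick(t), ob.parse_newick(t)])
    assert m.n_columns == 4  # two informative clades per copy


def test_mrp_matches_hand_enumeration():
    m = ob.mrp_encode([ob.parse_newick("(A,(B,C));"), ob.parse_newick("((A,B),D);")])
    assert m.taxa == ["A", "B", "C", "D"]
    cols = {tuple(m.data[:, j]) for j in range(m.n_columns)}
    # clade {B,C} from tree 1 (D unscored), clade {A,B} from tree 2 (C unscored)
    assert cols == {(0, 1, 1, -1), (1, 1, -1, 0)}


def test_mrp_skips_tiny_trees():
    m = ob.mrp_encode([ob.parse_newick("(A,B);"), ob.parse_newick("(A,(B,C));")])
    assert m.n_columns == 1
    assert m.taxa == ["A", "B", "C"]  # 2-tip tree contributes nothing


def test_supertree_recovers_single_source_tree(rng):
    src = random_tree(rng, [f"t{i}" for i in range(7)])
    res = ob.build_supertree(ob.mrp_encode([src]), n_restarts=8, seed=1)
    assert ob.bipartitions(res.tree) == ob.bipartitions(src)


def _restricted_bipartitions(tree, taxa):
    """Bipartitions of the tree induced on a taxon subset (display check)."""
    taxa = set(taxa)
    out = set()
    anchor = min(taxa)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = {l.taxon.label for l in node.leaf_iter()} & taxa
        if len(clade) < 2 or len(taxa - clade) < 2:
            continue
        out.add(frozenset(taxa - clade) if anchor in clade else frozenset(clade))
    return out


def test_supertree_displays_compatible_sources():
    t1 = ob.parse_newick("((A,B),((C,D),(E,F)));")
    t2 = ob.parse_newick("((A,B),(C,E));")
    res = ob.build_supertree(ob.mrp_encode([t1, t2]), n_restarts=10, seed=2)
    for src in (t1, t2):
        taxa = ob.tip_labels(src)
        assert ob.bipartitions(src) <= _restricted_bipartitions(res.tree, taxa)


def _all_unrooted_trees(n_taxa):
    """Exhaustive enumeration of unrooted binary topologies (as search nodes)."""

    def leaf(i):
        return _N(taxon=i)

    trees = [_N(children=[leaf(0), _N(children=[leaf(1), leaf(2)])])]
    for t in range(3, n_taxa):
        new = []
        for tr in trees:
            for parent, i in _edges(tr):
                import copy

                tr2 = copy.deepcopy(tr)
                # find corresponding edge in the copy by position
                for (p2, i2), (p1, i1) in zip(_edges(tr2), _edges(tr)):
                    if p1 is parent and i1 == i:
                        old = p2.children[i2]
                        p2.children[i2] = _N(children=[old, leaf(t)])
                        break
                new.append(tr2)
        trees = new
    return trees


def test_supertree_matches_exhaustive_parsimony_on_5_taxa(rng):
    src1 = random_tree(rng, ["a", "b", "c", "d", "e"])
    src2 = random_tree(rng, ["a", "b", "c", "d", "e"])
    m = ob.mrp_encode([src1, src2])
    res = ob.build_supertree(m, n_restarts=10, seed=3)
    ts = np.where(m.data == 1, 2, np.where(m.data == 0, 1, 3)).astype(np.uint8)
    scores = [_fitch_score(tr, ts) for tr in _all_unrooted_trees(5)]
    assert len(scores) == 15
    assert res.score == min(scores)


def test_supertree_rejects_disjoint_taxon_sets():
    m = ob.mrp_encode([ob.parse_newick("(A,(B,C));"), ob.parse_newick("(X,(Y,Z));")])
    with pytest.raises(ValueError, match="backbone"):
        ob.build_supertree(m, seed=0)
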