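"""Phylogenetic machinery: newick I/O, MRP supertree assembly, and the
branch-based diversity metrics (Faith PD, PhyloSor, phylogenetic weighted
endemism).

Branch lengths are not comparable across source trees digitized from the
literature, so the pipeline runs on unit branch lengths throughout
(:func:`set_unit_branch_lengths`).  All metrics use the tip-to-root-inclusive
convention: the minimal subtree spanning an assemblage contains every edge on
the path from each tip to the root.  This makes PD of a single tip equal to
its depth, makes the grid-wide sum of phylogenetic weighted endemism equal
the total branch length exactly, and leaves PhyloSor well defined for
single-species assemblages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core_data import HexGrid, PresenceMatrix, Surface

logger = logging.getLogger(__name__)

#: a cell's community: any collection of species ids
Assemblage = Iterable[str]


# ---------------------------------------------------------------------------
# Newick I/O and branch lengths
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted tree from a newick file; duplicate tip labels are an error."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error classes
        raise ValueError(f"cannot parse newick file {path}: {exc}") from exc
    _check_tips(tree)
    return tree


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string (same contract as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"cannot parse newick: {exc}") from exc
    _check_tips(tree)
    return tree


def _check_tips(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def set_unit_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Return a clone of ``tree`` with every edge length set to exactly 1.0."""
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.head_node is not out.seed_node:
            edge.length = 1.0
        else:
            edge.length = None  # the root has no parent edge
    return out


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions (unrooted sense) as normalized tip sets.

    Each internal edge splits the tips in two; the side *not* containing the
    alphabetically first tip is reported, so rooting does not matter.
    """
    tips = set(tip_labels(tree))
    anchor = min(tips)
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(clade) < 2 or len(tips) - len(clade) < 2:
            continue
        side = frozenset(tips - clade) if anchor in clade else clade
        out.add(side)
    return out


# ---------------------------------------------------------------------------
# Edge table: the workhorse behind all branch-based metrics
# ---------------------------------------------------------------------------


@dataclass
class EdgeTable:
    """Flat view of a tree: per non-root edge, its length and descendant tips."""

    tips: list[str]  # sorted
    lengths: np.ndarray  # (n_edges,)
    below: np.ndarray  # (n_edges, n_tips) bool: tip descends from edge

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "EdgeTable":
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        idx = {t: i for i, t in enumerate(tips)}
        lengths, below = [], []
        masks: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                m = np.zeros(len(tips), dtype=bool)
                m[idx[node.taxon.label]] = True
            else:
                m = np.zeros(len(tips), dtype=bool)
                for ch in node.child_nodes():
                    m |= masks[id(ch)]
            masks[id(node)] = m
            if node.parent_node is not None:
                ln = node.edge.length
                lengths.append(1.0 if ln is None else float(ln))
                below.append(m)
        return cls(tips=tips, lengths=np.asarray(lengths, float), below=np.asarray(below, bool))

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def tip_mask(self, assemblage: Assemblage) -> np.ndarray:
        idx = {t: i for i, t in enumerate(self.tips)}
        m = np.zeros(len(self.tips), dtype=bool)
        dropped = 0
        for s in assemblage:
            if s in idx:
                m[idx[s]] = True
            else:
                dropped += 1
        if dropped:
            logger.info("assemblage: %d species not on the tree were dropped", dropped)
        return m


def faith_pd(assemblage: Assemblage, tree: dendropy.Tree | EdgeTable) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    root-inclusive subtree spanning the assemblage's tips."""
    et = tree if isinstance(tree, EdgeTable) else EdgeTable.from_tree(tree)
    m = et.tip_mask(assemblage)
    if not m.any():
        logger.warning("faith_pd: assemblage shares no species with the tree; PD = 0")
        return 0.0
    on_path = et.below[:, m].any(axis=1)
    return float(et.lengths[on_path].sum())


def phylosor(a: Assemblage, b: Assemblage, tree: dendropy.Tree | EdgeTable) -> float:
    """PhyloSor similarity: shared branch length over the mean of the two PDs.

    The dissimilarity used downstream is ``1 - phylosor(a, b, tree)``.
    """
    et = tree if isinstance(tree, EdgeTable) else EdgeTable.from_tree(tree)
    ma, mb = et.tip_mask(a), et.tip_mask(b)
    if not ma.any() or not mb.any():
        raise ValueError("phylosor is undefined for an empty assemblage")
    on_a = et.below[:, ma].any(axis=1)
    on_b = et.below[:, mb].any(axis=1)
    pd_a = float(et.lengths[on_a].sum())
    pd_b = float(et.lengths[on_b].sum())
    shared = float(et.lengths[on_a & on_b].sum())
    return shared / (0.5 * (pd_a + pd_b))


def branch_incidence(presence: PresenceMatrix, et: EdgeTable) -> tuple[np.ndarray, np.ndarray]:
    """(branch x cell occupancy, tip-presence submatrix) for shared tips.

    A branch occurs in a cell iff at least one of its descendant tips is
    present there.  Species absent from the tree are ignored (logged).
    """
    shared = [s for s in presence.species if s in set(et.tips)]
    if not shared:
        raise ValueError("presence matrix shares no species with the tree")
    n_missing = presence.n_species - len(shared)
    if n_missing:
        logger.info("branch_incidence: %d species not on the tree ignored", n_missing)
    sub = presence.data[shared].to_numpy()  # (cells, shared)
    cols = [et.tips.index(s) for s in shared]
    below = et.below[:, cols]  # (edges, shared)
    occ = below.astype(np.int32) @ sub.T.astype(np.int32) > 0  # (edges, cells)
    return occ, sub


def pwe_surface(presence: PresenceMatrix, tree: dendropy.Tree | EdgeTable, grid: HexGrid) -> Surface:
    """Phylogenetic weighted endemism per cell.

    Each branch ``b`` of the cell's minimal subtree contributes ``L_b / R_b``
    where ``R_b`` is the number of grid cells in which the branch occurs.
    Summed over all cells this returns exactly the total length of the
    branches represented in the matrix (conservation identity).
    """
    et = tree if isinstance(tree, EdgeTable) else EdgeTable.from_tree(tree)
    occ, _ = branch_incidence(presence, et)
    r_b = occ.sum(axis=1).astype(float)  # cells per branch
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(r_b > 0, et.lengths / np.where(r_b > 0, r_b, 1.0), 0.0)
    vals = share @ occ  # (cells,)
    return Surface.from_cells(grid, presence.cell_ids, vals)


# ---------------------------------------------------------------------------
# Matrix representation with parsimony (MRP)
# ---------------------------------------------------------------------------


@dataclass
class MRPMatrix:
    """Binary character matrix encoding clades of the source trees.

    ``data[i, j]`` is 1 if taxon ``i`` is inside column ``j``'s clade, 0 if it
    is in that source tree but outside the clade, and -1 (printed ``?``) if
    the taxon is absent from that tree.
    """

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_columns) int8
    provenance: list[tuple[int, int]]  # (source tree index, clade counter)
    tree_taxa: list[frozenset] = field(default_factory=list)  # taxa per source tree

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def to_text(self) -> str:
        """Relaxed PHYLIP-style export with ?-coding."""
        rows = [f"{self.n_taxa} {self.n_columns}"]
        sym = {1: "1", 0: "0", -1: "?"}
        for i, t in enumerate(self.taxa):
            rows.append(f"{t}  " + "".join(sym[int(v)] for v in self.data[i]))
        return "\n".join(rows) + "\n"


def mrp_encode(trees: Sequence[dendropy.Tree]) -> MRPMatrix:
    """Encode source trees as an MRP matrix: one column per non-trivial clade.

    Clades of size 1 and the root (all tips of a tree) are uninformative and
    skipped, as are trees with fewer than 3 tips (warned).
    """
    if not trees:
        raise ValueError("mrp_encode requires at least one tree")
    usable = []
    for t in trees:
        if len(tip_labels(t)) < 3:
            logger.warning("mrp_encode: tree with <3 tips skipped")
        else:
            usable.append(t)
    if not usable:
        raise ValueError("no usable source trees (all have <3 tips)")
    taxa = sorted(set(itertools.chain.from_iterable(tip_labels(t) for t in usable)))
    tidx = {t: i for i, t in enumerate(taxa)}
    cols, prov, tree_taxa = [], [], []
    for ti, tree in enumerate(usable):
        tips = set(tip_labels(tree))
        tree_taxa.append(frozenset(tips))
        ci = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = {l.taxon.label for l in node.leaf_iter()}
            if len(clade) < 2 or len(clade) >= len(tips):
                continue  # constant over scored taxa
            col = np.full(len(taxa), -1, dtype=np.int8)
            for s in tips:
                col[tidx[s]] = 1 if s in clade else 0
            cols.append(col)
            prov.append((ti, ci))
            ci += 1
    data = np.column_stack(cols) if cols else np.zeros((len(taxa), 0), np.int8)
    return MRPMatrix(taxa=taxa, data=data, provenance=prov, tree_taxa=tree_taxa)


# --- parsimony search -------------------------------------------------------


class _N:
    """Search-tree node: either a tip (taxon index) or an internal node."""

    __slots__ = ("children", "taxon")

    def __init__(self, taxon=None, children=None):
        self.taxon = taxon
        self.children = children if children is not None else []

    def is_leaf(self):
        return self.taxon is not None


def _postorder(root: _N) -> list[_N]:
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    out.reverse()
    return out


def _fitch_score(root: _N, tipstates: np.ndarray) -> int:
    """Fitch parsimony length over all characters.

    ``tipstates[t, c]`` is a 2-bit set: 1 = {0}, 2 = {1}, 3 = {0,1} (missing).
    """
    cost = 0
    states: dict[int, np.ndarray] = {}
    for node in _postorder(root):
        if node.is_leaf():
            states[id(node)] = tipstates[node.taxon]
        else:
            it = iter(node.children)
            acc = states[id(next(it))]
            for ch in it:
                s = states[id(ch)]
                inter = acc & s
                miss = inter == 0
                cost += int(miss.sum())
                acc = np.where(miss, acc | s, inter)
            states[id(node)] = acc
    return cost


def _edges(root: _N) -> list[tuple[_N, int]]:
    """All (parent, child index) pairs except the redundant second root edge."""
    out = []
    for node in _postorder(root):
        for i in range(len(node.children)):
            if node is root and i == 1:
                continue  # same unrooted edge as (root, 0)
            out.append((node, i))
    return out


def _copy_tree(node: _N) -> _N:
    if node.is_leaf():
        return _N(taxon=node.taxon)
    return _N(children=[_copy_tree(c) for c in node.children])


def _to_newick(node: _N, taxa: list[str]) -> str:
    if node.is_leaf():
        return taxa[node.taxon]
    return "(" + ",".join(_to_newick(c, taxa) for c in node.children) + ")"


@dataclass
class SupertreeResult:
    tree: dendropy.Tree
    score: int
    n_restarts: int


def _stepwise_addition(order: np.ndarray, tipstates: np.ndarray, rng) -> _N:
    root = _N(children=[_N(taxon=int(order[0])), _N(taxon=int(order[1]))])
    for t in order[2:]:
        best, best_score = None, None
        for parent, i in _edges(root):
            old = parent.children[i]
            parent.children[i] = _N(children=[old, _N(taxon=int(t))])
            sc = _fitch_score(root, tipstates)
            parent.children[i] = old
            if best_score is None or sc < best_score:
                best, best_score = (parent, i), sc
        parent, i = best
        old = parent.children[i]
        parent.children[i] = _N(children=[old, _N(taxon=int(t))])
    return root


def _nni_climb(root: _N, tipstates: np.ndarray, max_rounds: int = 200) -> tuple[_N, int]:
    score = _fitch_score(root, tipstates)
    for _ in range(max_rounds):
        improved = False
        for parent, i in _edges(root):
            child = parent.children[i]
            if child.is_leaf():
                continue
            sib_idx = 1 - i if len(parent.children) == 2 else None
            if sib_idx is None:
                continue
            for ci in range(len(child.children)):
                # swap sibling of `child` with one of child's children
                parent.children[sib_idx], child.children[ci] = child.children[ci], parent.children[sib_idx]
                sc = _fitch_score(root, tipstates)
                if sc < score:
                    score = sc
                    improved = True
                else:
                    parent.children[sib_idx], child.children[ci] = child.children[ci], parent.children[sib_idx]
        if not improved:
            break
    return root, score


def build_supertree(matrix: MRPMatrix, n_restarts: int = 10, seed: int = 0) -> SupertreeResult:
    """Heuristic MRP supertree: minimize Fitch parsimony length over the
    encoded clade matrix by random-addition stepwise insertion followed by
    NNI hill climbing, repeated ``n_restarts`` times from a fixed seed.
    """
    if matrix.n_taxa < 4:
        raise ValueError("supertree search requires at least 4 taxa")
    # source trees must overlap: otherwise their relative placement is free
    parent = list(range(len(matrix.tree_taxa)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(matrix.tree_taxa):
        for j, b in enumerate(matrix.tree_taxa[:i]):
            if a & b:
                parent[find(i)] = find(j)
    if len({find(i) for i in range(len(parent))}) > 1:
        raise ValueError(
            "source trees fall into disjoint taxon sets; add a common backbone tree linking them"
        )
    # tip states: rows taxa, cols characters, encoded as 2-bit sets
    ts = np.where(matrix.data == 1, 2, np.where(matrix.data == 0, 1, 3)).astype(np.uint8)
    rng = np.random.default_rng(seed)
    best_root, best_score = None, None
    for _ in range(n_restarts):
        order = rng.permutation(matrix.n_taxa)
        root = _stepwise_addition(order, ts, rng)
        root, score = _nni_climb(root, ts)
        if best_score is None or score < best_score:
            best_root, best_score = _copy_tree(root), score
    nwk = _to_newick(best_root, matrix.taxa) + ";"
    tree = parse_newick(nwk)
    tree = set_unit_branch_lengths(tree)
    logger.info("supertree: parsimony score %d after %d restarts", best_score, n_restarts)
    return SupertreeResult(tree=tree, score=int(best_score), n_restarts=n_restarts)
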