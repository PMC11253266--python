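"""Rooted dendrogram construction and evaluation.

Three tree builders, all agglomerative and rooted:

* :func:`upgma` — classic (un)weighted pair-group agglomeration with
  arithmetic mean on a precomputed distance matrix; merge height = d/2, so an
  exactly ultrametric input is reproduced cophenetically.
* :func:`string_merge_tree` — the stepwise sum-difference procedure on raw
  property waves: merge the closest pair (smallest L1 sum-difference), replace
  it by the positionwise mean of the two numeric strings, repeat.
* :func:`stat_merge_tree` — the same stepwise scheme on inverted pairwise
  similarity statistics (1/AMI, 1/autocorrelation), averaging the merged
  pair's distances to everyone else.

Trees serialize to Newick, and two quality-control evaluators are provided:
exact monophyly of a named group, and a 0/1 match of the dendrogram's leaf
ordering (up to planar rotation) against an expected ranking of taxa or
taxon groups.

Ties are broken deterministically everywhere: among equally close pairs, the
pair whose sorted pair of representative labels (lexicographically smallest
leaf of each cluster) is smallest merges first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distances import DistanceMatrix, sum_difference
from .exceptions import DimensionError, PropseqError
from .simstats import PairStatTable, stat_to_distance


@dataclass(frozen=True)
class Node:
    """A dendrogram node: a leaf (name, height 0) or a merge of two children."""

    height: float
    name: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        """Leaf nodes in planar (left-to-right) order."""
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> tuple:
        return tuple(l.name for l in self.leaves())


@dataclass(frozen=True)
class Dendrogram:
    """A rooted merge tree with node heights (root height maximal)."""

    root: Node

    @property
    def leaf_names(self) -> tuple:
        return self.root.leaf_names()

    def clades(self) -> set:
        """Frozensets of leaf names below each internal node (incl. root)."""
        out = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            s = frozenset().union(*(walk(c) for c in node.children))
            out.add(s)
            return s

        walk(self.root)
        return out

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise leaf distances: twice the height of the lowest common ancestor."""
        taxa = tuple(sorted(self.leaf_names))
        idx = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        d = np.zeros((n, n))

        def walk(node: Node) -> list:
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return [x for g in groups for x in g]

        walk(self.root)
        return DistanceMatrix(taxa, d, "cophenetic")


def to_newick(tree: Dendrogram, precision: int = 10) -> str:
    """Newick text with branch lengths = parent height - child height.

    Height inversions (possible in the stepwise merge procedures) are clamped
    to zero-length branches.
    """

    def fmt(v: float) -> str:
        return f"{v:.{precision}g}"

    def walk(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            label = node.name
        else:
            label = "(" + ",".join(walk(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return label
        return f"{label}:{fmt(max(parent_height - node.height, 0.0))}"

    return walk(tree.root, None) + ";"


def from_newick(text: str) -> Dendrogram:
    """Parse a rooted Newick string (with branch lengths) into a Dendrogram.

    Node heights are reconstructed from depths: the root sits at the maximum
    leaf depth and every node's height is that depth minus its own.
    """
    import io as _io

    from Bio import Phylo

    clade_tree = Phylo.read(_io.StringIO(text), "newick")
    root = clade_tree.root

    depths = {}

    def depth_walk(clade, depth):
        depths[id(clade)] = depth
        for child in clade.clades:
            depth_walk(child, depth + (child.branch_length or 0.0))

    depth_walk(root, 0.0)
    max_depth = max(
        depths[id(c)] for c in clade_tree.find_clades() if not c.clades
    )

    def build(clade) -> Node:
        h = max_depth - depths[id(clade)]
        if not clade.clades:
            return Node(h, name=str(clade.name))
        return Node(h, children=tuple(build(c) for c in clade.clades))

    return Dendrogram(build(root))


# --------------------------------------------------------------------------
# Agglomeration engine
# --------------------------------------------------------------------------

def _rep(node: Node) -> str:
    return min(node.leaf_names())


def _pick_pair(dist: dict, clusters: dict) -> tuple:
    """Minimal-distance pair; ties by lexicographically smallest sorted label pair."""
    best_key = None
    best = None
    for (i, j), v in dist.items():
        label = tuple(sorted((_rep(clusters[i]), _rep(clusters[j]))))
        key = (v, label)
        if best_key is None or key < best_key:
            best_key = key
            best = (i, j)
    return best


def _agglomerate(taxa: Sequence[str], d: np.ndarray, update, height_fn) -> Dendrogram:
    """Generic agglomeration: repeatedly merge the closest pair.

    ``update(dik, djk, ni, nj)`` gives the merged cluster's distance to a
    third cluster; ``height_fn(dij)`` the merge height.  Heights are made
    monotone (parent >= children) by clamping.
    """
    n = len(taxa)
    clusters = {i: Node(0.0, name=taxa[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        i, j = _pick_pair(dist, clusters)
        dij = dist[(i, j)]
        a, b = clusters[i], clusters[j]
        # deterministic child order: representative-label order
        left, right = (a, b) if _rep(a) <= _rep(b) else (b, a)
        h = max(height_fn(dij), a.height, b.height)
        merged = Node(h, children=(left, right))
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = update(
                dik, djk, sizes[i], sizes[j]
            )
        for k in list(dist):
            if i in k or j in k:
                del dist[k]
        del clusters[i], clusters[j]
        sizes[next_id] = sizes.pop(i) + sizes.pop(j)
        clusters[next_id] = merged
        next_id += 1
    return Dendrogram(next(iter(clusters.values())))


def upgma(D: DistanceMatrix, weighting: str = "unweighted") -> Dendrogram:
    """Pair-group agglomeration with arithmetic mean (UPGMA / WPGMA).

    ``weighting="unweighted"`` (UPGMA) averages cluster-to-cluster distances
    weighted by cluster sizes; ``"weighted"`` (WPGMA) takes the simple mean
    of the merged pair's distances.  Merge height is d/2, so the result is
    ultrametric and reproduces an exactly ultrametric input.
    """
    if weighting == "unweighted":
        update = lambda dik, djk, ni, nj: (ni * dik + nj * djk) / (ni + nj)
    elif weighting == "weighted":
        update = lambda dik, djk, ni, nj: (dik + djk) / 2.0
    else:
        raise PropseqError(f"unknown weighting {weighting!r}")
    if D.n_taxa < 2:
        raise DimensionError("need at least 2 taxa")
    return _agglomerate(D.taxa, D.d, update, lambda dij: dij / 2.0)


def string_merge_tree(waves) -> Dendrogram:
    """Stepwise sum-difference tree from raw property waves.

    At each step the pair of numeric strings with the smallest L1
    sum-difference merges (height = sum-difference / 2) and is replaced by
    the positionwise arithmetic mean of the two strings.
    """
    waves = list(waves)
    if len(waves) < 2:
        raise DimensionError("need at least 2 waves")
    m = len(waves[0].values)
    for w in waves:
        if len(w.values) != m:
            raise DimensionError("waves have unequal lengths")
    clusters = {i: Node(0.0, name=w.taxon) for i, w in enumerate(waves)}
    strings = {i: np.asarray(w.values, dtype=float) for i, w in enumerate(waves)}
    next_id = len(waves)
    while len(clusters) > 1:
        dist = {}
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                dist[(i, j)] = sum_difference(strings[i], strings[j])
        i, j = _pick_pair(dist, clusters)
        dij = dist[(i, j)]
        a, b = clusters[i], clusters[j]
        left, right = (a, b) if _rep(a) <= _rep(b) else (b, a)
        h = max(dij / 2.0, a.height, b.height)
        clusters[next_id] = Node(h, children=(left, right))
        strings[next_id] = (strings[i] + strings[j]) / 2.0
        for k in (i, j):
            del clusters[k], strings[k]
        next_id += 1
    return Dendrogram(next(iter(clusters.values())))


def stat_merge_tree(stat: PairStatTable, transform: str = "inverse") -> Dendrogram:
    """Stepwise tree from inverted pairwise statistics (1/AMI, 1/autocorrelation).

    The statistic table is transformed to distances, then the closest pair
    merges and its distances to each remaining taxon are replaced by their
    arithmetic mean (WPGMA-style on the transformed values).
    """
    D = stat_to_distance(stat, transform)
    return _agglomerate(
        D.taxa, D.d, lambda dik, djk, ni, nj: (dik + djk) / 2.0, lambda dij: dij / 2.0
    )


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def is_monophyletic(tree: Dendrogram, group: Iterable[str]) -> bool:
    """True iff some node's leaf set equals the group exactly."""
    group = frozenset(group)
    leaves = frozenset(tree.leaf_names)
    unknown = group - leaves
    if unknown:
        raise PropseqError(f"unknown labels: {sorted(unknown)}")
    if len(group) == 1:
        return True
    return group in tree.clades()


def _normalize_expectation(expected) -> list:
    items = []
    for item in expected:
        if isinstance(item, str):
            items.append(frozenset([item]))
        else:
            items.append(frozenset(item))
    flat = [l for g in items for l in g]
    if len(flat) != len(set(flat)):
        raise PropseqError("expectation groups are not disjoint")
    return items


def ranking_match(tree: Dendrogram, expected) -> int:
    """0/1 score of a tree against an expected taxon ranking.

    ``expected`` is an ordered list of labels and/or groups of labels
    (e.g. ``[{"human", "mouse"}, {"gecko", "turtle"}]``).  The score is 1 iff
    every multi-member group is monophyletic and some planar rotation of the
    dendrogram lists the leaves so that earlier items precede later ones
    (within-group order free); else 0.
    """
    items = _normalize_expectation(expected)
    leaves = frozenset(tree.leaf_names)
    mentioned = frozenset(l for g in items for l in g)
    unknown = mentioned - leaves
    if unknown:
        raise PropseqError(f"unknown labels: {sorted(unknown)}")
    for g in items:
        if len(g) > 1 and not is_monophyletic(tree, g):
            return 0
    rank = {label: i for i, g in enumerate(items) for label in g}

    def feasible(node: Node) -> tuple:
        """(ok, min_rank, max_rank) over mentioned leaves under some rotation."""
        if node.is_leaf:
            r = rank.get(node.name)
            return True, r, r
        ok_l, lo_l, hi_l = feasible(node.children[0])
        ok_r, lo_r, hi_r = feasible(node.children[1])
        if not (ok_l and ok_r):
            return False, None, None
        if lo_l is None:
            return True, lo_r, hi_r
        if lo_r is None:
            return True, lo_l, hi_l
        ok = hi_l <= lo_r or hi_r <= lo_l
        return ok, min(lo_l, lo_r), max(hi_l, hi_r)

    return 1 if feasible(tree.root)[0] else 0


def ranking_report(trees: dict, expected) -> "pd.DataFrame":
    """Per-tree 0/1 table of ranking matches (one row per named tree)."""
    import pandas as pd

    rows = [(name, ranking_match(t, expected)) for name, t in trees.items()]
    return pd.DataFrame(rows, columns=["tree", "match"]).set_index("tree")
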