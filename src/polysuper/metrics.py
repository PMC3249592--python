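"""Supertree accuracy and resolution measures.

Given a model tree and a reconstructed supertree on a common leaf set, the
package reports:

* normalized Robinson-Foulds distance: |C1 symdiff C2| / (|C1| + |C2|) over
  nontrivial clades (size >= 2, proper subsets of the leaf set),
* the triplet distance: every 3-subset of leaves falls into one of five bins
  (resolved identically, resolved differently, resolved only in the first or
  only in the second tree, unresolved in both) and

      d_TR = (diff + r1 + r2) / (same + diff + r1 + r2),

* the rooted maximum agreement subtree (MAST) score: the largest leaf set on
  which restrictions of the two trees coincide, normalized by the model
  tree's leaf count,
* resolution: nontrivial clade count / (n - 2), i.e. 0 for a star and 1 for
  a fully resolved binary tree.

Nonplenary supertrees are compared after restricting the model tree to the
supertree's taxa; only the MAST normalization keeps the full model leaf
count, so pruning taxa cannot inflate that score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .tree import RootedTree, TreeError, lca_depth_matrix, restrict


@dataclass
class TripletComparison:
    """Counts of the five outcomes of comparing all leaf triples."""

    same: int = 0
    diff: int = 0
    r1: int = 0  # resolved only in the first tree
    r2: int = 0  # resolved only in the second tree
    x: int = 0  # unresolved in both

    @property
    def total(self) -> int:
        return self.same + self.diff + self.r1 + self.r2 + self.x

    @property
    def d_tr(self) -> float:
        denom = self.same + self.diff + self.r1 + self.r2
        if denom == 0:
            return 0.0  # two stars: identical by convention
        return (self.diff + self.r1 + self.r2) / denom


@dataclass
class ComparisonReport:
    """Per-replicate comparison record between a model tree and a supertree."""

    resolution: float
    rf_norm: float
    triplet: TripletComparison
    mast_size: int
    mast_norm: float
    n_excluded_taxa: int = 0

    @property
    def d_tr(self) -> float:
        return self.triplet.d_tr


def _require_same_leaves(t1: RootedTree, t2: RootedTree) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        raise TreeError("trees must have identical leaf sets; restrict first")


def rf_distance(t1: RootedTree, t2: RootedTree) -> float:
    """Normalized Robinson-Foulds distance over nontrivial clades, in [0, 1].

    Two star trees (both clade sets empty) get distance 0 by continuity.
    """
    _require_same_leaves(t1, t2)
    c1, c2 = t1.clades(), t2.clades()
    denom = len(c1) + len(c2)
    if denom == 0:
        return 0.0
    return len(c1 ^ c2) / denom


def resolution(tree: RootedTree) -> float:
    """Nontrivial clade count relative to the n - 2 of a binary tree."""
    n = tree.n_leaves
    if n < 3:
        raise TreeError("resolution requires at least 3 leaves")
    return len(tree.clades()) / (n - 2)


def triplet_comparison(t1: RootedTree, t2: RootedTree) -> TripletComparison:
    """Classify every 3-subset of the common leaf set.

    Uses lca-depth matrices: among the three pairwise lca depths of a triple,
    the two smallest are always equal; the triple is resolved iff the largest
    is unique, and the maximizing pair is the cherry.
    """
    _require_same_leaves(t1, t2)
    order = sorted(t1.leaf_labels)
    n = len(order)
    result = TripletComparison()
    if n < 3:
        return result
    D1 = lca_depth_matrix(t1, order)
    D2 = lca_depth_matrix(t2, order)

    def classify(a, b, c):
        # returns (resolved mask, cherry code 0=xy 1=xz 2=yz)
        m = np.maximum(np.maximum(a, b), c)
        resolved = ~((a == m) & (b == m) & (c == m))
        cherry = np.where(a == m, 0, np.where(b == m, 1, 2))
        return resolved, cherry

    same = diff = r1 = r2 = xx = 0
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            a1, a2 = D1[i, j], D2[i, j]
            b1, b2 = D1[i, j + 1 :], D2[i, j + 1 :]
            c1, c2 = D1[j, j + 1 :], D2[j, j + 1 :]
            res1, ch1 = classify(np.full_like(b1, a1), b1, c1)
            res2, ch2 = classify(np.full_like(b2, a2), b2, c2)
            both = res1 & res2
            agree = both & (ch1 == ch2)
            same += int(agree.sum())
            diff += int((both & ~agree).sum())
            r1 += int((res1 & ~res2).sum())
            r2 += int((res2 & ~res1).sum())
            xx += int((~res1 & ~res2).sum())
    result.same, result.diff, result.r1, result.r2, result.x = same, diff, r1, r2, xx
    return result


def triplet_distance(t1: RootedTree, t2: RootedTree) -> float:
    return triplet_comparison(t1, t2).d_tr


def mast_score(t1: RootedTree, t2: RootedTree) -> tuple[int, float]:
    """Rooted maximum agreement subtree size and its normalization.

    Dynamic program over node pairs; polytomies are handled by a
    maximum-weight assignment between child lists.  The score is normalized
    by the leaf count of ``t1`` (the model tree).
    """
    nodes1 = list(t1.postorder())
    nodes2 = list(t2.postorder())
    idx1 = {id(v): i for i, v in enumerate(nodes1)}
    idx2 = {id(w): i for i, w in enumerate(nodes2)}
    leaves_below1 = _leafsets(t1)
    leaves_below2 = _leafsets(t2)
    M = np.zeros((len(nodes1), len(nodes2)), dtype=np.int64)
    for v in nodes1:
        vi = idx1[id(v)]
        for w in nodes2:
            wi = idx2[id(w)]
            if v.is_leaf and w.is_leaf:
                M[vi, wi] = 1 if v.label == w.label else 0
            elif v.is_leaf:
                M[vi, wi] = 1 if v.label in leaves_below2[id(w)] else 0
            elif w.is_leaf:
                M[vi, wi] = 1 if w.label in leaves_below1[id(v)] else 0
            else:
                best = 0
                for c in v.children:
                    best = max(best, M[idx1[id(c)], wi])
                for d in w.children:
                    best = max(best, M[vi, idx2[id(d)]])
                sub = M[np.ix_([idx1[id(c)] for c in v.children], [idx2[id(d)] for d in w.children])]
                ri, ci = linear_sum_assignment(sub, maximize=True)
                best = max(best, int(sub[ri, ci].sum()))
                M[vi, wi] = best
    size = int(M[idx1[id(t1.root)], idx2[id(t2.root)]])
    return size, size / t1.n_leaves


def _leafsets(tree: RootedTree) -> dict[int, frozenset[str]]:
    out: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[id(node)] = frozenset([node.label])
        else:
            out[id(node)] = frozenset().union(*(out[id(c)] for c in node.children))
    return out


def compare_nonplenary(model: RootedTree, supertree: RootedTree) -> ComparisonReport:
    """Full comparison record; handles supertrees missing model taxa.

    RF, triplet and resolution are computed against the model restricted to
    the supertree's leaves; the MAST score is normalized by the *full* model
    leaf count so that dropping taxa is penalized.
    """
    if not supertree.leaf_labels <= model.leaf_labels:
        raise TreeError("supertree contains taxa absent from the model tree")
    restricted = (
        model
        if supertree.leaf_labels == model.leaf_labels
        else restrict(model, supertree.leaf_labels)
    )
    trip = triplet_comparison(restricted, supertree)
    mast_size, _ = mast_score(restricted, supertree)
    return ComparisonReport(
        resolution=resolution(supertree) if supertree.n_leaves >= 3 else 0.0,
        rf_norm=rf_distance(restricted, supertree),
        triplet=trip,
        mast_size=mast_size,
        mast_norm=mast_size / model.n_leaves,
        n_excluded_taxa=model.n_leaves - supertree.n_leaves,
    )
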