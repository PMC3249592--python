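"""Rooted phylogenetic trees: data model, Newick I/O, and primitive operations.

This module is the currency of the whole package.  A :class:`RootedTree` is a
rooted phylogenetic tree with uniquely labeled leaves and optional nonnegative
branch lengths (in expected substitutions per site).  On top of it we provide
the primitives every supertree algorithm consumes: restriction to a taxon
subset, last common ancestors, path lengths, resolved-triplet extraction, and
the *display* relation between trees.

Conventions
-----------
* After construction every non-root internal node has out-degree >= 2
  (degree-two chains are suppressed, summing branch lengths), and for trees
  with >= 2 leaves the root has out-degree >= 2.
* Leaf-label comparison is exact byte equality; no case folding.
* Trees are treated as immutable once constructed; operations return copies.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, NamedTuple

import dendropy
import numpy as np


class TreeError(ValueError):
    """Invalid tree structure or invalid arguments to a tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class Node:
    """A node of a rooted tree; leaves carry labels, edges carry lengths."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length  # length of the edge to the parent; None on the root
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Triplet(NamedTuple):
    """A resolved rooted triplet xy|z: cherry pair {x, y}, outlier z.

    Stored canonically with ``x < y`` so equality ignores cherry ordering.
    """

    x: str
    y: str
    z: str

    @classmethod
    def of(cls, a: str, b: str, z: str) -> "Triplet":
        if a == b or a == z or b == z:
            raise TreeError(f"triplet labels must be distinct: {a!r}, {b!r}, {z!r}")
        if b < a:
            a, b = b, a
        return cls(a, b, z)


class RootedTree:
    """A rooted phylogenetic tree with labeled leaves.

    Parameters
    ----------
    root:
        Root node of a parent/children structure.  Degree-two chains are
        suppressed in place (their branch lengths summed) and the structure is
        validated: unique nonempty leaf labels, nonnegative branch lengths.
    """

    __slots__ = ("root", "_leaves")

    def __init__(self, root: Node):
        root.parent = None
        self.root = _suppress_unifurcations(root)
        self._leaves: dict[str, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf without a label")
                if node.label in self._leaves:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                self._leaves[node.label] = node
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length} above {node.label!r}")

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(self._leaves)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def leaf(self, label: str) -> Node:
        try:
            return self._leaves[label]
        except KeyError:
            raise TreeError(f"no leaf labeled {label!r}") from None

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n is not self.root)

    def copy(self) -> "RootedTree":
        return RootedTree(_clone(self.root))

    # -- clades ------------------------------------------------------------

    def clade_of(self, node: Node) -> frozenset[str]:
        """Leaf labels descending from ``node``."""
        labels = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    def clades(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Clades of the tree as leaf-label sets.

        With ``nontrivial=True`` (default) only clades of size >= 2 that are
        proper subsets of the full leaf set are returned — the clades counted
        by the comparison metrics.
        """
        all_leaves = self.leaf_labels
        out: set[frozenset[str]] = set()
        clade_below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                clade_below[id(node)] = frozenset([node.label])
            else:
                cl = frozenset().union(*(clade_below[id(c)] for c in node.children))
                clade_below[id(node)] = cl
                if nontrivial:
                    if len(cl) >= 2 and cl != all_leaves:
                        out.add(cl)
                else:
                    out.add(cl)
        if not nontrivial:
            out.update(frozenset([lab]) for lab in all_leaves)
        return out

    def newick(self, precision: int = 10) -> str:
        return write_newick(self, precision=precision)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        s = self.newick()
        return f"RootedTree({s if len(s) < 60 else s[:57] + '...'})"


# ---------------------------------------------------------------------------
# construction helpers


def _suppress_unifurcations(root: Node) -> Node:
    """Splice out non-root out-degree-1 nodes; collapse root chains."""
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    stack = [root]
    while stack:
        node = stack.pop()
        new_children: list[Node] = []
        for child in node.children:
            while len(child.children) == 1:
                grand = child.children[0]
                if grand.length is not None or child.length is not None:
                    grand.length = (grand.length or 0.0) + (child.length or 0.0)
                child = grand
            child.parent = node
            new_children.append(child)
            stack.append(child)
        node.children = new_children
    return root


def _clone(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add_child(_clone(child))
    return new


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy)


def parse_newick(text: str, clamp_negative: bool = False) -> RootedTree:
    """Parse a single Newick string into a :class:`RootedTree`.

    Quoted labels and scientific-notation branch lengths are accepted;
    internal node labels are parsed but ignored by all algorithms.  With
    ``clamp_negative=True`` negative branch lengths (as neighbor joining can
    produce) are clamped to zero instead of rejected.
    """
    trees = parse_newick_list(text, clamp_negative=clamp_negative)
    if len(trees) != 1:
        raise NewickParseError(f"expected exactly one tree, found {len(trees)}")
    return trees[0]


def parse_newick_list(text: str, clamp_negative: bool = False) -> list[RootedTree]:
    """Parse one or more semicolon-terminated Newick trees."""
    if ";" not in text:
        raise NewickParseError("missing terminating semicolon")
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from None
    if len(tlist) == 0:
        raise NewickParseError("no tree found in input")
    return [_from_dendropy(t, clamp_negative) for t in tlist]


def _from_dendropy(dtree: "dendropy.Tree", clamp_negative: bool = False) -> RootedTree:
    def length_of(dnode):
        length = dnode.edge.length
        if clamp_negative and length is not None and length < 0:
            length = 0.0
        return length

    def conv(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label, length_of(dnode))
        else:
            node = Node(dnode.label, length_of(dnode))
            for child in dnode.child_nodes():
                node.add_child(conv(child))
        return node

    return RootedTree(conv(dtree.seed_node))


_QUOTE_TRIGGERS = set(" \t\n()[]{}':;,=")


def _format_label(label: str) -> str:
    if label and not (_QUOTE_TRIGGERS & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: RootedTree, precision: int = 10) -> str:
    """Serialize to Newick with branch lengths at ``precision`` significant digits."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = _format_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += _format_label(node.label)
        if node.length is not None and node.parent is not None:
            s += ":" + f"%.{precision}g" % node.length
        return s

    return fmt(tree.root) + ";"


def read_trees(path) -> list[RootedTree]:
    with open(path) as fh:
        return parse_newick_list(fh.read())


def write_trees(trees: Iterable[RootedTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick() + "\n")


# ---------------------------------------------------------------------------
# primitive operations


def _check_subset(tree: RootedTree, labels: Iterable[str]) -> frozenset[str]:
    X = frozenset(labels)
    missing = X - tree.leaf_labels
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")
    if not X:
        raise TreeError("empty label set")
    return X


def restrict(tree: RootedTree, labels: Iterable[str]) -> RootedTree:
    """Restriction T|X: minimal subtree spanning X with degree-two vertices
    suppressed.  Branch lengths through suppressed chains are summed, so path
    lengths between retained leaves are preserved."""
    X = _check_subset(tree, labels)

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.label in X:
                return Node(node.label, node.length)
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            if only.length is not None or node.length is not None:
                only.length = (only.length or 0.0) + (node.length or 0.0)
            return only
        new = Node(node.label, node.length)
        for c in kept:
            new.add_child(c)
        return new

    root = rec(tree.root)
    assert root is not None
    root.length = None
    return RootedTree(root)


def lca(tree: RootedTree, labels: Iterable[str]) -> Node:
    """Deepest node whose clade contains all of ``labels``."""
    X = _check_subset(tree, labels)
    nodes = [tree.leaf(lab) for lab in X]
    current = nodes[0]
    for other in nodes[1:]:
        current = _lca_pair(current, other)
    return current


def _depth(node: Node) -> int:
    d = 0
    while node.parent is not None:
        node = node.parent
        d += 1
    return d


def _lca_pair(a: Node, b: Node) -> Node:
    da, db = _depth(a), _depth(b)
    while da > db:
        a = a.parent
        da -= 1
    while db > da:
        b = b.parent
        db -= 1
    while a is not b:
        a = a.parent
        b = b.parent
    return a


def path_length(tree: RootedTree, x: str, y: str) -> float:
    """pl(x, y): sum of branch lengths along the path between leaves x and y."""
    if x == y:
        tree.leaf(x)
        return 0.0
    anc = lca(tree, [x, y])
    total = 0.0
    for leaf_label in (x, y):
        node = tree.leaf(leaf_label)
        while node is not anc:
            if node.length is None:
                raise TreeError(f"missing branch length on the {x}-{y} path")
            total += node.length
            node = node.parent
    return total


def depth_to_ancestor(tree: RootedTree, leaf_label: str, ancestor: Node) -> float:
    """Path length from a leaf up to one of its ancestors."""
    node = tree.leaf(leaf_label)
    total = 0.0
    while node is not ancestor:
        if node.length is None:
            raise TreeError(f"missing branch length above {leaf_label!r}")
        total += node.length
        node = node.parent
        if node is None:
            raise TreeError(f"{ancestor!r} is not an ancestor of {leaf_label!r}")
    return total


def triplets(tree: RootedTree) -> set[Triplet]:
    """All resolved rooted triplets rt(T).

    xy|z is in rt(T) iff lca(x, y) is a proper descendant of lca(x, y, z).
    Triples spanned by a polytomy are unresolved and omitted; a binary tree on
    n leaves has exactly C(n, 3) triplets.
    """
    all_leaves = tree.leaf_labels
    out: set[Triplet] = set()
    clade_below: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clade_below[id(node)] = [node.label]
        else:
            groups = [clade_below[id(c)] for c in node.children]
            merged = [lab for g in groups for lab in g]
            outside = all_leaves.difference(merged)
            for ga, gb in itertools.combinations(groups, 2):
                for a in ga:
                    for b in gb:
                        for z in outside:
                            out.add(Triplet.of(a, b, z))
            clade_below[id(node)] = merged
    return out


def displays(big: RootedTree, small: RootedTree) -> bool:
    """True iff ``big`` displays ``small``: big|L(small) refines small.

    Refinement on a common leaf set is clade containment, so we check that
    every nontrivial clade of ``small`` is a clade of the restriction.
    """
    if not small.leaf_labels <= big.leaf_labels:
        raise TreeError("displays: L(small) must be a subset of L(big)")
    restricted = restrict(big, small.leaf_labels)
    return small.clades() <= restricted.clades()


def topologically_equal(t1: RootedTree, t2: RootedTree) -> bool:
    """Equal leaf sets and identical clade structure (child order ignored)."""
    return t1.leaf_labels == t2.leaf_labels and t1.clades() == t2.clades()


# ---------------------------------------------------------------------------
# matrix utilities shared by the metrics and simulation modules


def lca_depth_matrix(tree: RootedTree, order: list[str]) -> np.ndarray:
    """Matrix of topological lca depths (edges from the root) over ``order``.

    ``M[i, j]`` is the depth of lca(order[i], order[j]); the diagonal holds
    leaf depths.  Used for O(1) triplet classification.
    """
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    M = np.zeros((n, n), dtype=np.int64)
    depth: dict[int, int] = {id(tree.root): 0}
    for node in tree.preorder():
        for child in node.children:
            depth[id(child)] = depth[id(node)] + 1
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = idx.get(node.label)
            below[id(node)] = [i] if i is not None else []
            if i is not None:
                M[i, i] = depth[id(node)]
        else:
            groups = [below[id(c)] for c in node.children]
            d = depth[id(node)]
            for ga, gb in itertools.combinations(groups, 2):
                for i in ga:
                    M[i, gb] = d
                    M[gb, i] = d
            below[id(node)] = [i for g in groups for i in g]
    return M


def leaf_distance_matrix(tree: RootedTree, order: list[str] | None = None):
    """Pairwise path-length matrix between leaves (requires branch lengths)."""
    if order is None:
        order = sorted(tree.leaf_labels)
    idx = {lab: i for i, lab in enumerate(order)}
    n = len(order)
    D = np.zeros((n, n))
    dist: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        for child in node.children:
            if child.length is None:
                raise TreeError("leaf_distance_matrix requires branch lengths")
            dist[id(child)] = dist[id(node)] + child.length
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = idx.get(node.label)
            below[id(node)] = [i] if i is not None else []
        else:
            groups = [below[id(c)] for c in node.children]
            d = dist[id(node)]
            for ga, gb in itertools.combinations(groups, 2):
                for i in ga:
                    di = dist[id(tree.leaf(order[i]))]
                    for j in gb:
                        dj = dist[id(tree.leaf(order[j]))]
                        D[i, j] = D[j, i] = di + dj - 2.0 * d
            below[id(node)] = [i for g in groups for i in g]
    return order, D


def root_with_outgroup(tree: RootedTree, outgroup: str, prune: bool = False) -> RootedTree:
    """Re-root a tree on the pendant edge of ``outgroup``.

    The result has a root with two children: the outgroup leaf (keeping its
    pendant length) and the rest of the tree.  Useful for rooting trees whose
    basal trifurcation marks an unrooted estimate (e.g. neighbor joining).
    With ``prune=True`` the outgroup is removed again after rooting.
    """
    tree.leaf(outgroup)
    work = tree.copy()
    og = work.leaf(outgroup)
    parent = og.parent
    if parent is None:
        raise TreeError("cannot root on a single-leaf tree")
    if parent.parent is None and len(parent.children) == 2:
        rooted = work  # already rooted on the outgroup edge
    else:
        parent.children.remove(og)
        _reverse_to_root(parent)
        new_root = Node()
        parent.length = 0.0
        new_root.add_child(og)
        new_root.add_child(parent)
        rooted = RootedTree(new_root)
    if prune:
        return restrict(rooted, rooted.leaf_labels - {outgroup})
    return rooted


def _reverse_to_root(node: Node) -> None:
    """Reverse parent pointers so ``node`` becomes a root (in place)."""
    chain: list[Node] = []
    cur: Node | None = node
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    original_lengths = [n.length for n in chain]
    for i, (lower, upper) in enumerate(zip(chain, chain[1:])):
        upper.children.remove(lower)
        lower.add_child(upper)
        upper.length = original_lengths[i]
    node.parent = None
    node.length = None
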