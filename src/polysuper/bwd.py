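"""Build-with-Distances (BWD) supertrees.

BWD follows the recursive Build schema but additionally exploits branch
lengths of the input trees.  Its ingredients:

* the lambda table: for an ordered leaf pair (x, y), lambda(x, y) is the
  distance from x up to lca(x, y), averaged over the input trees containing
  both.  lambda is *not* symmetric.
* the BWD graph: the Build graph plus *distance edges*.  If x and y co-occur
  in some tree, x and z in another, no tree contains all three, and
  lambda(x, y) < lambda(x, z), then {x, y} is an edge even without a
  supporting triplet.
* primary evidence p(x, y, z) = max{0, lambda(x, z) - lambda(x, y)} (zero
  when {x, y} or {x, z} never co-occur): evidence that x belongs with y
  rather than z.
* support functions weighting the edges of a connected BWD graph over the
  current clade U:

      SAC(x, y, U)     = sum_z min{p(x, y, z), p(y, x, z)}
      SAC_max(x, y, U) = sum_z max{p(x, y, z), p(y, x, z)}

  with z ranging over U \\ {x, y}.
* the bisection rule: find the smallest threshold theta such that deleting
  every edge of weight <= theta disconnects the graph; the resulting
  components become the child clades.

Unlike MC/MMC, BWD does not guarantee to return the parent tree for
compatible inputs: distance signal may overrule topology.  All supports scale
linearly with the branch lengths, so a common rescaling of all input trees
leaves the output topology unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal

import numpy as np

from .build import build_graph
from .tree import RootedTree, TreeError

SupportName = Literal["sac", "sacmax"]


@dataclass
class LambdaTable:
    """Averaged leaf-to-lca distances over a tree collection.

    ``lam[i, j]`` is lambda(labels[i], labels[j]) (NaN when the pair never
    co-occurs); ``cooccur`` counts trees containing both; ``joint`` packs,
    per pair, the bitmask union of the leaf sets of the trees containing the
    pair (used by the cross-tree edge rule).
    """

    labels: list[str]
    index: dict[str, int]
    lam: np.ndarray
    cooccur: np.ndarray
    joint: np.ndarray  # uint64, shape (n, n, n_chunks)

    def lambda_of(self, x: str, y: str) -> float:
        v = self.lam[self.index[x], self.index[y]]
        if np.isnan(v):
            raise TreeError(f"lambda({x!r}, {y!r}) undefined: pair never co-occurs")
        return float(v)

    def cooccur_of(self, x: str, y: str) -> int:
        return int(self.cooccur[self.index[x], self.index[y]])


def _tree_lambda(tree: RootedTree, index: dict[str, int], lam_sum, count, joint, mask_chunks):
    """Accumulate one tree's leaf-to-lca distances into the global tables."""
    dist: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        for child in node.children:
            if child.length is None:
                raise TreeError("lambda table requires branch lengths on every tree")
            dist[id(child)] = dist[id(node)] + child.length
    below: dict[int, list[int]] = {}
    leafdist: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = index[node.label]
            below[id(node)] = [i]
            leafdist[i] = dist[id(node)]
        else:
            groups = [below[id(c)] for c in node.children]
            d = dist[id(node)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        for j in groups[gj]:
                            lam_sum[i, j] += leafdist[i] - d
                            lam_sum[j, i] += leafdist[j] - d
                            count[i, j] += 1
                            count[j, i] += 1
                            joint[i, j] |= mask_chunks
                            joint[j, i] |= mask_chunks
            below[id(node)] = [i for g in groups for i in g]


def lambda_table(trees: Iterable[RootedTree]) -> LambdaTable:
    """Compute lambda once from the full input trees (not per recursion)."""
    trees = list(trees)
    labels = sorted(set().union(*(t.leaf_labels for t in trees)))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    n_chunks = (n + 63) // 64
    lam_sum = np.zeros((n, n))
    count = np.zeros((n, n), dtype=np.int64)
    joint = np.zeros((n, n, n_chunks), dtype=np.uint64)
    for tree in trees:
        mask_chunks = np.zeros(n_chunks, dtype=np.uint64)
        for lab in tree.leaf_labels:
            i = index[lab]
            mask_chunks[i >> 6] |= np.uint64(1) << np.uint64(i & 63)
        _tree_lambda(tree, index, lam_sum, count, joint, mask_chunks)
    with np.errstate(invalid="ignore"):
        lam = np.where(count > 0, lam_sum / np.maximum(count, 1), np.nan)
    return LambdaTable(labels, index, lam, count, joint)


def primary_evidence(table: LambdaTable, x: str, y: str, z: str) -> float:
    """p(x, y, z) = max{0, lambda(x, z) - lambda(x, y)}; 0 when either pair
    never co-occurs."""
    if len({x, y, z}) != 3:
        raise TreeError("primary evidence requires three distinct labels")
    if table.cooccur_of(x, y) == 0 or table.cooccur_of(x, z) == 0:
        return 0.0
    return max(0.0, table.lambda_of(x, z) - table.lambda_of(x, y))


def _evidence_vector(table: LambdaTable, xi: int, yi: int, zi: np.ndarray) -> np.ndarray:
    """p(x, y, z) for fixed ordered (x, y) and a vector of outliers z."""
    if table.cooccur[xi, yi] == 0:
        return np.zeros(len(zi))
    p = table.lam[xi, zi] - table.lam[xi, yi]
    p = np.nan_to_num(p, nan=0.0)
    p[table.cooccur[xi, zi] == 0] = 0.0
    return np.maximum(p, 0.0)


def _support(table: LambdaTable, x: str, y: str, taxa: Iterable[str], agg) -> float:
    U = set(taxa)
    if x == y or x not in U or y not in U:
        raise TreeError("support functions require two distinct members of U")
    xi, yi = table.index[x], table.index[y]
    zi = np.array([table.index[z] for z in U if z != x and z != y], dtype=np.int64)
    if len(zi) == 0:
        return 0.0
    pxy = _evidence_vector(table, xi, yi, zi)
    pyx = _evidence_vector(table, yi, xi, zi)
    return float(agg(pxy, pyx).sum())


def support_sac(table: LambdaTable, x: str, y: str, taxa: Iterable[str]) -> float:
    """Accumulated confirmed support: sum of min{p(x,y,z), p(y,x,z)} over U."""
    return _support(table, x, y, taxa, np.minimum)


def support_sac_max(table: LambdaTable, x: str, y: str, taxa: Iterable[str]) -> float:
    """Optimistic variant: sum of max{p(x,y,z), p(y,x,z)} over U."""
    return _support(table, x, y, taxa, np.maximum)


_SUPPORTS: dict[str, Callable] = {"sac": np.minimum, "sacmax": np.maximum}


@dataclass
class BwdGraph:
    """BWD graph over a taxon set: Build edges plus cross-tree distance edges."""

    vertices: frozenset[str]
    edges: dict[frozenset[str], str]  # provenance: "build" or "distance"

    def components(self) -> list[list[str]]:
        parent = {v: v for v in self.vertices}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for e in self.edges:
            a, b = tuple(e)
            parent[find(a)] = find(b)
        comps: dict[str, list[str]] = {}
        for v in self.vertices:
            comps.setdefault(find(v), []).append(v)
        out = [sorted(c) for c in comps.values()]
        out.sort(key=lambda c: c[0])
        return out


def bwd_graph(trees: list[RootedTree], table: LambdaTable, taxa: Iterable[str]) -> BwdGraph:
    """Build graph over ``taxa`` extended by the distance-edge rule."""
    U = frozenset(taxa)
    base = build_graph(trees, U)
    edges: dict[frozenset[str], str] = {e: "build" for e in base.edges}

    members = sorted(U)
    idx = np.array([table.index[lab] for lab in members], dtype=np.int64)
    chunk = idx >> 6
    bit = np.uint64(1) << (idx & 63).astype(np.uint64)
    lam = table.lam
    co = table.cooccur
    for a_pos in range(len(members)):
        ai = idx[a_pos]
        for b_pos in range(a_pos + 1, len(members)):
            bi = idx[b_pos]
            pair = frozenset((members[a_pos], members[b_pos]))
            if pair in edges or co[ai, bi] == 0:
                continue
            # z in U co-occurring with a (or b) but never in one tree with both
            in_joint = (table.joint[ai, bi, chunk] & bit) != 0
            for xi, yi in ((ai, bi), (bi, ai)):
                cand = (~in_joint) & (co[xi, idx] >= 1)
                cand[a_pos] = cand[b_pos] = False
                if np.any(lam[xi, idx[cand]] > lam[xi, yi]):
                    edges[pair] = "distance"
                    break
    return BwdGraph(U, edges)


def bisection_disconnect(
    weights: dict[frozenset[str], float], taxa: Iterable[str]
) -> tuple[float, list[list[str]]]:
    """Smallest threshold theta whose removal of edges with w <= theta
    disconnects the graph, together with the resulting components.

    theta equals the bottleneck of the graph: the minimum edge weight on a
    maximum spanning tree.  If the graph does not connect ``taxa`` at all the
    caller has made an error.
    """
    U = sorted(set(taxa))
    if len(U) < 2:
        raise TreeError("bisection needs at least two vertices")
    parent = {v: v for v in U}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    # Kruskal on descending weights; the weight closing the last component
    # is the bottleneck theta.
    order = sorted(weights.items(), key=lambda item: (-item[1], sorted(item[0])))
    n_comp = len(U)
    theta = None
    for e, w in order:
        a, b = tuple(e)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            n_comp -= 1
            if n_comp == 1:
                theta = w
                break
    if theta is None:
        raise TreeError("bisection called on a disconnected graph")

    survivor = {v: v for v in U}

    def find2(v):
        while survivor[v] != v:
            survivor[v] = survivor[survivor[v]]
            v = survivor[v]
        return v

    for e, w in weights.items():
        if w > theta:
            a, b = tuple(e)
            survivor[find2(a)] = find2(b)
    comps: dict[str, list[str]] = {}
    for v in U:
        comps.setdefault(find2(v), []).append(v)
    out = [sorted(c) for c in comps.values()]
    out.sort(key=lambda c: c[0])
    return theta, out


def bwd_supertree(trees: list[RootedTree], support: SupportName = "sac") -> RootedTree:
    """BWD supertree with the chosen support function ("sac" or "sacmax").

    Always returns a plenary tree on the union of the input leaf sets.
    """
    if support not in _SUPPORTS:
        raise ValueError(f"unknown support function {support!r}")
    agg = _SUPPORTS[support]
    if not trees:
        raise ValueError("need at least one input tree")
    for t in trees:
        if not t.has_branch_lengths():
            raise TreeError("BWD requires branch lengths on every input tree")
    table = lambda_table(trees)
    all_taxa = frozenset(table.labels)

    from .tree import Node

    def rec(U: frozenset[str]) -> Node:
        if len(U) == 1:
            (lab,) = U
            return Node(lab)
        if len(U) == 2:
            node = Node()
            for lab in sorted(U):
                node.add_child(Node(lab))
            return node
        graph = bwd_graph(trees, table, U)
        comps = graph.components()
        if len(comps) == 1:
            weights = {}
            zi_all = np.array([table.index[z] for z in sorted(U)], dtype=np.int64)
            for e in graph.edges:
                x, y = tuple(e)
                xi, yi = table.index[x], table.index[y]
                zi = zi_all[(zi_all != xi) & (zi_all != yi)]
                pxy = _evidence_vector(table, xi, yi, zi)
                pyx = _evidence_vector(table, yi, xi, zi)
                weights[e] = float(agg(pxy, pyx).sum())
            _, comps = bisection_disconnect(weights, U)
        node = Node()
        for comp in comps:
            node.add_child(rec(frozenset(comp)))
        return node

    return RootedTree(rec(all_taxa))
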