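"""Graph-based rooted supertrees: Build, MinCut (MC), and Modified MinCut (MMC).

All three methods share one recursive schema.  On the current taxon set U a
*Build graph* is formed: vertices are the taxa of U, and {x, y} is an edge
whenever some input tree, restricted to U, resolves x and y together below its
root (equivalently, contributes a triplet xy|z).  If the graph is
disconnected, its components become the child clades and the recursion
descends; Build declares the inputs incompatible when the graph is connected,
while MC and MMC disconnect it by deleting minimum-weight cuts.

Edge bookkeeping per pair {x, y} over the restricted trees that contain both:

* ``n_cooccur``   — number of restricted trees containing both x and y,
* ``weight``      — number of those placing lca(x, y) below their root
  (supporting trees),
* ``n_contradict``— number placing lca(x, y) at their root (contradicting
  trees), so ``weight + n_contradict == n_cooccur``.

MC contracts edges supported by *every* tree alive at the current level, then
deletes every edge lying in at least one global minimum cut of the contracted
weighted graph (the all-minimum-cuts rule makes the output invariant under
input order and relabeling).  MMC instead protects every uncontradicted edge
from deletion by contracting it, so that any input clade no tree disagrees
with survives into the supertree; only contradicted edges can be cut.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .tree import Node, RootedTree, restrict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Incompatible:
    """Distinguished Build result: no supertree displays all inputs.

    ``taxa`` is the taxon set of the recursion level at which the Build graph
    stayed connected.
    """

    taxa: frozenset[str]

    def __bool__(self) -> bool:
        return False


@dataclass
class EdgeInfo:
    weight: int = 0
    n_cooccur: int = 0
    n_contradict: int = 0


@dataclass
class SupertreeGraph:
    """Weighted Build graph over a taxon set U with per-edge bookkeeping.

    ``edges`` holds only supported pairs (weight >= 1); ``pair_stats`` also
    retains co-occurring pairs that no tree supports (pure contradictions).
    ``n_trees`` counts the restricted input trees able to express support
    (>= 3 leaves within U) — the unanimity reference for MC contraction.
    """

    vertices: frozenset[str]
    edges: dict[frozenset[str], EdgeInfo] = field(default_factory=dict)
    pair_stats: dict[frozenset[str], EdgeInfo] = field(default_factory=dict)
    n_trees: int = 0

    def components(self) -> list[list[str]]:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
        return comps


def build_graph(trees: Iterable[RootedTree], taxa: Iterable[str]) -> SupertreeGraph:
    """Build graph over ``taxa``: each tree is restricted to its share of the
    taxon set first, then votes on every leaf pair it retains."""
    U = frozenset(taxa)
    graph = SupertreeGraph(vertices=U)
    for tree in trees:
        shared = U & tree.leaf_labels
        if len(shared) < 2:
            continue
        rt = tree if shared == tree.leaf_labels else restrict(tree, shared)
        if len(shared) >= 3:
            graph.n_trees += 1
        # pairs inside one root-child clade have lca below the root: support;
        # pairs spanning two root children have lca at the root: contradiction
        groups = [sorted(rt.clade_of(c)) for c in rt.root.children]
        for gi in range(len(groups)):
            for a_idx in range(len(groups[gi])):
                a = groups[gi][a_idx]
                for b in groups[gi][a_idx + 1 :]:
                    info = graph.pair_stats.setdefault(frozenset((a, b)), EdgeInfo())
                    info.n_cooccur += 1
                    info.weight += 1
                for gj in range(gi + 1, len(groups)):
                    for b in groups[gj]:
                        info = graph.pair_stats.setdefault(frozenset((a, b)), EdgeInfo())
                        info.n_cooccur += 1
                        info.n_contradict += 1
    graph.edges = {e: info for e, info in graph.pair_stats.items() if info.weight >= 1}
    return graph


# ---------------------------------------------------------------------------
# Build


def build_supertree(trees: list[RootedTree]) -> RootedTree | Incompatible:
    """The all-or-nothing Build algorithm.

    Returns a supertree on L(T) displaying every input tree when the
    collection is compatible, else an :class:`Incompatible` marker.
    """
    _check_inputs(trees)
    all_taxa = frozenset().union(*(t.leaf_labels for t in trees))

    def rec(U: frozenset[str]) -> Node | Incompatible:
        node_or_leaf = _trivial_level(U)
        if node_or_leaf is not None:
            return node_or_leaf
        comps = build_graph(trees, U).components()
        if len(comps) == 1:
            return Incompatible(U)
        node = Node()
        for comp in comps:
            child = rec(frozenset(comp))
            if isinstance(child, Incompatible):
                return child
            node.add_child(child)
        return node

    result = rec(all_taxa)
    if isinstance(result, Incompatible):
        return result
    return RootedTree(result)


def _check_inputs(trees: list[RootedTree]) -> None:
    if not trees:
        raise ValueError("need at least one input tree")
    for t in trees:
        if t.n_leaves < 2:
            raise ValueError("input trees must have at least 2 leaves")


def _trivial_level(U: frozenset[str]) -> Node | None:
    if len(U) == 1:
        (label,) = U
        return Node(label)
    if len(U) == 2:
        node = Node()
        for label in sorted(U):
            node.add_child(Node(label))
        return node
    return None


# ---------------------------------------------------------------------------
# MC / MMC


def mincut_supertree(trees: list[RootedTree]) -> RootedTree:
    """MinCut supertree: Build with minimum-cut conflict resolution.

    Always returns a plenary tree; on compatible inputs it coincides with
    Build (the connected-graph event never occurs) and so displays every
    input tree.
    """
    return _cut_supertree(trees, mmc=False)


def modified_mincut_supertree(trees: list[RootedTree]) -> RootedTree:
    """Modified MinCut supertree.

    Differs from MC in which edges a cut may delete: every uncontradicted
    edge is contracted (never separated), so each input clade with which no
    single tree disagrees appears in the output.
    """
    return _cut_supertree(trees, mmc=True)


def _cut_supertree(trees: list[RootedTree], mmc: bool) -> RootedTree:
    _check_inputs(trees)
    all_taxa = frozenset().union(*(t.leaf_labels for t in trees))

    def rec(U: frozenset[str]) -> Node:
        trivial = _trivial_level(U)
        if trivial is not None:
            return trivial
        graph = build_graph(trees, U)
        comps = graph.components()
        if len(comps) == 1:
            comps = _disconnect(graph, mmc=mmc)
            if len(comps) == 1:
                # contraction merged everything: unresolvable conflict corner
                warnings.warn(
                    "contraction collapsed a conflicting component; emitting a "
                    f"polytomy over {len(U)} taxa",
                    stacklevel=2,
                )
                node = Node()
                for label in sorted(U):
                    node.add_child(Node(label))
                return node
        node = Node()
        for comp in comps:
            node.add_child(rec(frozenset(comp)))
        return node

    return RootedTree(rec(all_taxa))


def _disconnect(graph: SupertreeGraph, mmc: bool) -> list[list[str]]:
    """Delete the union of all global minimum cuts of the contracted graph.

    Returns the components of the (uncontracted) graph after deletion; a
    single component signals contraction collapse.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.vertices)
    for e, info in graph.edges.items():
        a, b = tuple(e)
        g.add_edge(a, b, weight=info.weight)

    if mmc:
        protected = {e for e, info in graph.edges.items() if info.n_contradict == 0}
    else:
        protected = {
            e
            for e, info in graph.edges.items()
            if graph.n_trees > 0 and info.weight == graph.n_trees
        }

    # contract protected edges into supervertices
    merged = nx.Graph()
    uf = nx.utils.UnionFind(graph.vertices)
    for e in protected:
        a, b = tuple(e)
        uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for v in graph.vertices:
        groups.setdefault(uf[v], []).append(v)
    canon = {root: min(members) for root, members in groups.items()}
    rep = {v: canon[uf[v]] for v in graph.vertices}

    merged.add_nodes_from(set(rep.values()))
    for e, info in graph.edges.items():
        a, b = tuple(e)
        ra, rb = rep[a], rep[b]
        if ra == rb:
            continue
        if merged.has_edge(ra, rb):
            merged[ra][rb]["weight"] += info.weight
        else:
            merged.add_edge(ra, rb, weight=info.weight)

    if merged.number_of_nodes() == 1:
        return [sorted(graph.vertices)]
    if not nx.is_connected(merged):  # pragma: no cover - caller guarantees
        comps = [sorted(c) for c in nx.connected_components(merged)]
    else:
        cut_edges = _all_min_cut_edges(merged)
        to_delete = set()
        for ra, rb in cut_edges:
            ga, gb = set(groups_of(rep, ra)), set(groups_of(rep, rb))
            for e in graph.edges:
                x, y = tuple(e)
                if (x in ga and y in gb) or (x in gb and y in ga):
                    to_delete.add(e)
        residual = nx.Graph()
        residual.add_nodes_from(graph.vertices)
        for e in graph.edges:
            if e not in to_delete:
                a, b = tuple(e)
                residual.add_edge(a, b)
        comps = [sorted(c) for c in nx.connected_components(residual)]
    comps.sort(key=lambda c: c[0])
    return comps


def groups_of(rep: dict[str, str], representative: str) -> list[str]:
    return [v for v, r in rep.items() if r == representative]


def _all_min_cut_edges(g: nx.Graph) -> list[tuple[str, str]]:
    """Edges lying in at least one global minimum cut of a weighted graph.

    An edge {a, b} crosses some global minimum cut iff the minimum a-b cut
    weight equals the global minimum cut weight (any cut separating a from b
    necessarily contains the edge).  All pairwise minimum-cut weights come
    from one Gomory-Hu tree: the a-b cut weight is the smallest flow on the
    a-b path of that tree, and the global minimum is the tree's smallest
    flow overall.
    """
    import igraph as ig

    if g.number_of_nodes() < 2:
        return []
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edge_list = list(g.edges(data=True))
    graph = ig.Graph(
        n=len(nodes), edges=[(index[a], index[b]) for a, b, _ in edge_list]
    )
    caps = [float(data["weight"]) for _, _, data in edge_list]
    gh = graph.gomory_hu_tree(capacity=caps, flow="flow")
    flows = gh.es["flow"]
    global_cut = min(flows)
    adj: list[list[tuple[int, float]]] = [[] for _ in nodes]
    for e in gh.es:
        adj[e.source].append((e.target, e["flow"]))
        adj[e.target].append((e.source, e["flow"]))

    def path_min(src: int, dst: int) -> float:
        # DFS on the Gomory-Hu tree tracking the smallest flow en route
        stack = [(src, -1, float("inf"))]
        while stack:
            v, parent, lo = stack.pop()
            if v == dst:
                return lo
            for w, f in adj[v]:
                if w != parent:
                    stack.append((w, v, min(lo, f)))
        raise RuntimeError("disconnected Gomory-Hu tree")  # pragma: no cover

    out = []
    for a, b, _ in edge_list:
        if path_min(index[a], index[b]) <= global_cut + 1e-9:
            out.append((a, b))
    return out
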