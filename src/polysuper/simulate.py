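"""Benchmark input generation: Yule model trees, rate deviation, outgroup
attachment, GTR+Gamma+I sequence evolution, taxon deletion, and input-tree
reconstruction.

The generator emulates the classic supertree benchmarking scheme: a model
tree is drawn from a pure-birth (Yule) process; branch durations are turned
into substitution branch lengths by branch-specific rate multipliers (normal,
mean 1.0, sd 0.5, truncated to [0.1, 2.0]) times a tree-wide rate; an
outgroup is attached above the root for rooting; per input tree a fraction of
taxa is deleted; and the input tree is either the clean restriction of the
model tree, a neighbor-joining reconstruction from a simulated sequence
block, or an NNI-perturbed restriction.

Every random choice flows from one seed, so a configuration reproduces its
trees and sequences bit-exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .reconcile import p_distance_matrix
from .tree import (
    Node,
    RootedTree,
    TreeError,
    leaf_distance_matrix,
    parse_newick,
    restrict,
    root_with_outgroup,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# model parameters


@dataclass(frozen=True)
class GtrParams:
    """General time reversible model with Gamma rate heterogeneity and a
    proportion of invariant sites.

    Defaults follow a published mammalian-alignment estimate: base
    frequencies in order (A, C, G, T), exchangeabilities in order
    (AC, AG, AT, CG, CT, GT) with GT fixed to 1, Gamma shape alpha, and the
    invariant-site proportion.
    """

    freqs: tuple[float, float, float, float] = (0.3468, 0.3594, 0.0805, 0.2133)
    rates: tuple[float, float, float, float, float, float] = (
        0.6750,
        27.9597,
        1.1677,
        0.4547,
        20.8760,
        1.0,
    )
    gamma_shape: float = 1.1999
    p_invariant: float = 0.4954

    def __post_init__(self):
        if any(f <= 0 for f in self.freqs) or abs(sum(self.freqs) - 1.0) > 1e-6:
            raise ValueError("base frequencies must be positive and sum to 1")
        if any(r <= 0 for r in self.rates):
            raise ValueError("exchangeabilities must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("invariant proportion must lie in [0, 1)")

    def rate_matrix(self) -> np.ndarray:
        """GTR rate matrix Q normalized to one expected substitution per unit
        branch length at stationarity."""
        ac, ag, at, cg, ct, gt = self.rates
        pi = np.array(self.freqs)
        S = np.array(
            [
                [0.0, ac, ag, at],
                [ac, 0.0, cg, ct],
                [ag, cg, 0.0, gt],
                [at, ct, gt, 0.0],
            ]
        )
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu


@dataclass
class SimulationConfig:
    """One benchmark setting: model-tree size, taxon deletion, input count.

    ``block_length`` defaults to 1000 bp up to 144 taxa and 500 bp beyond,
    matching the study conditions the generator emulates.
    """

    n_taxa: int = 96
    deletion_ratio: float = 0.5
    n_input_trees: int = 10
    input_mode: str = "clean_restriction"  # clean_restriction | sequence_nj | nni_perturb
    block_length: int | None = None
    tree_wide_rate: float | None = None
    nni_moves: int = 2
    gtr: GtrParams = field(default_factory=GtrParams)
    outgroup: str = "OUT"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.deletion_ratio < 1.0:
            raise ValueError("deletion ratio must lie in [0, 1)")
        if self.n_input_trees < 2:
            raise ValueError("need at least 2 input trees")
        if self.input_mode not in ("clean_restriction", "sequence_nj", "nni_perturb"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.block_length is None:
            self.block_length = 1000 if self.n_taxa <= 144 else 500


# ---------------------------------------------------------------------------
# model trees


def yule_tree(n: int, seed) -> RootedTree:
    """Rooted binary tree from a unit-rate pure-birth process.

    Branch lengths are lineage durations (time units).  Leaves are labeled
    t1..tn in order of appearance; the process runs one extra waiting time
    after the n-th lineage arises so the final cherry has positive pendant
    edges.  The tree is ultrametric.
    """
    if n < 3:
        raise ValueError("need at least 3 taxa")
    rng = _as_rng(seed)
    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = []
    for _ in range(2):
        child = root.add_child(Node())
        active.append((child, 0.0))
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node, birth = active.pop(int(rng.integers(k)))
        node.length = t - birth
        for _ in range(2):
            child = node.add_child(Node())
            active.append((child, t))
    t += rng.exponential(1.0 / n)
    for i, (node, birth) in enumerate(active):
        node.label = f"t{i + 1}"
        node.length = t - birth
    return RootedTree(root)


def _truncated_normal(rng: np.random.Generator, mean=1.0, sd=0.5, lo=0.1, hi=2.0) -> float:
    while True:  # rejection sampling matches the truncation exactly
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x


def default_tree_rate(n: int, target_height: float = 0.3) -> float:
    """Tree-wide substitution rate so the expected root-to-tip path of a
    unit-rate Yule tree on n taxa is about ``target_height`` subs/site."""
    expected_height = sum(1.0 / k for k in range(2, n + 1)) + 1.0 / n
    return target_height / expected_height


def deviate_rates(tree: RootedTree, tree_wide_rate: float, seed) -> RootedTree:
    """Deviate a clock tree: per-branch length = duration x r x rate with
    r ~ Normal(1.0, 0.5) truncated to [0.1, 2.0]."""
    rng = _as_rng(seed)

    def rec(node: Node) -> Node:
        length = node.length
        if length is not None:
            length = length * _truncated_normal(rng) * tree_wide_rate
        new = Node(node.label, length)
        for child in node.children:
            new.add_child(rec(child))
        return new

    return RootedTree(rec(tree.root))


def add_outgroup(tree: RootedTree, label: str = "OUT") -> RootedTree:
    """Attach an outgroup above the root with pendant length 1.25 x d_max.

    d_max is the largest pairwise distance of the taxon farthest from all
    others.  If that taxon's d_max exceeds the runner-up taxon's maximum
    distance by more than 75%, its pendant branch is first shortened until
    the excess is exactly 75%.
    """
    if label in tree.leaf_labels:
        raise TreeError(f"outgroup label {label!r} already present")
    work = tree.copy()
    order, D = leaf_distance_matrix(work)
    totals = D.sum(axis=1)
    ranked = np.argsort(-totals)
    far = int(ranked[0])
    d_max = float(D[far].max())
    if len(ranked) > 1:
        runner_up_max = float(D[int(ranked[1])].max())
        if runner_up_max > 0 and d_max > 1.75 * runner_up_max:
            excess = d_max - 1.75 * runner_up_max
            pendant = work.leaf(order[far])
            shrink = min(excess, pendant.length or 0.0)
            pendant.length = (pendant.length or 0.0) - shrink
            d_max -= shrink
            logger.warning(
                "shortened pendant branch of %s by %.4g to bound the outgroup distance",
                order[far],
                shrink,
            )
    new_root = Node()
    old_root = work.root
    old_root.length = 0.0
    new_root.add_child(old_root)
    new_root.add_child(Node(label, 1.25 * d_max))
    return RootedTree(new_root)


def delete_taxa(tree: RootedTree, ratio: float, seed, keep=frozenset()) -> RootedTree:
    """Remove a uniformly random fraction of the deletable taxa.

    ``keep`` (typically the outgroup) is never deleted; floor(ratio * m)
    taxa are removed from the m deletable ones.
    """
    if not 0.0 <= ratio < 1.0:
        raise ValueError("deletion ratio must lie in [0, 1)")
    rng = _as_rng(seed)
    keep = frozenset(keep)
    deletable = sorted(tree.leaf_labels - keep)
    n_delete = math.floor(ratio * len(deletable))
    if tree.n_leaves - n_delete < 3:
        raise TreeError("deletion would leave fewer than 3 taxa")
    doomed = set(rng.choice(deletable, size=n_delete, replace=False)) if n_delete else set()
    return restrict(tree, tree.leaf_labels - doomed)


# ---------------------------------------------------------------------------
# sequence evolution


@dataclass
class Alignment:
    """Equal-length nucleotide sequences encoded as uint8 codes 0..3 (ACGT)."""

    sequences: dict[str, np.ndarray]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> list[str]:
        return sorted(self.sequences)

    def subset(self, labels) -> "Alignment":
        labels = set(labels)
        missing = labels - set(self.sequences)
        if missing:
            raise KeyError(f"taxa not in alignment: {sorted(missing)}")
        return Alignment({t: s for t, s in self.sequences.items() if t in labels})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                seq = "".join(BASES[c] for c in self.sequences[taxon])
                fh.write(f">{taxon}\n{seq}\n")


def evolve_sequences(tree: RootedTree, length: int, params: GtrParams, seed) -> Alignment:
    """Simulate sequences along a tree under GTR + Gamma + invariant sites.

    Branch lengths are expected substitutions per site at the mean rate.
    Each site is invariant with probability p_inv; variable sites draw a
    Gamma(alpha) rate rescaled by 1/(1 - p_inv) so the mean site rate is 1.
    The root sequence is drawn from the stationary frequencies.
    """
    if not tree.has_branch_lengths():
        raise TreeError("sequence simulation requires branch lengths")
    rng = _as_rng(seed)
    pi = np.array(params.freqs)
    Q = params.rate_matrix()
    # reversible Q diagonalizes symmetrically: B = D^1/2 Q D^-1/2
    sqrt_pi = np.sqrt(pi)
    B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    eigvals, V = np.linalg.eigh((B + B.T) / 2.0)
    left = V / sqrt_pi[:, None]  # P(t) = left @ diag(e^{lambda t}) @ right
    right = V.T * sqrt_pi[None, :]

    rates = np.where(
        rng.random(length) < params.p_invariant,
        0.0,
        rng.gamma(params.gamma_shape, 1.0 / params.gamma_shape, size=length)
        / (1.0 - params.p_invariant),
    )

    sequences: dict[str, np.ndarray] = {}
    state: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=length, p=pi).astype(np.uint8)
    }
    for node in tree.preorder():
        parent_seq = state[id(node)]
        for child in node.children:
            expo = np.exp(eigvals[None, :] * (rates * child.length)[:, None])
            # per-site transition row for the parent state
            temp = left[parent_seq, :] * expo
            probs = temp @ right
            np.clip(probs, 0.0, None, out=probs)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(length)
            child_seq = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)
            state[id(child)] = child_seq
            if child.is_leaf:
                sequences[child.label] = child_seq
    return Alignment(sequences)


# ---------------------------------------------------------------------------
# input-tree reconstruction


def nj_tree(alignment: Alignment, outgroup: str) -> RootedTree:
    """Neighbor joining on Jukes-Cantor distances, rooted on the outgroup
    branch; the outgroup is pruned from the result.

    Deterministic given the alignment (taxa are processed in sorted order).
    Negative estimated branch lengths are clamped to zero.
    """
    if outgroup not in alignment.sequences:
        raise TreeError(f"outgroup {outgroup!r} missing from alignment")
    if len(alignment.sequences) < 3:
        raise TreeError("neighbor joining needs at least 3 sequences")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    dm = p_distance_matrix(alignment.sequences, jukes_cantor=True)
    if not np.all(np.isfinite(dm.values)):
        raise TreeError("degenerate distances in neighbor joining input")
    sk = skbio_nj(SkbioDM(dm.values, ids=dm.taxa))
    unrooted = parse_newick(str(sk), clamp_negative=True)
    return root_with_outgroup(unrooted, outgroup, prune=True)


def nni_perturb(tree: RootedTree, k: int, seed) -> RootedTree:
    """Apply k uniform-random nearest-neighbor-interchange moves."""
    rng = _as_rng(seed)
    work = tree.copy()
    for _ in range(k):
        candidates = [
            v
            for v in work.internal_nodes()
            if v.parent is not None and len(v.parent.children) >= 2
        ]
        if not candidates:
            break
        v = candidates[int(rng.integers(len(candidates)))]
        u = v.parent
        siblings = [s for s in u.children if s is not v]
        s = siblings[int(rng.integers(len(siblings)))]
        c = v.children[int(rng.integers(len(v.children)))]
        # swap subtrees c (below v) and s (below u)
        v.children[v.children.index(c)] = s
        u.children[u.children.index(s)] = c
        s.parent, c.parent = v, u
        work = RootedTree(work.root)
    return work


def make_input_trees(config: SimulationConfig) -> tuple[RootedTree, list[RootedTree]]:
    """Generate one replicate: the model tree (with outgroup) and its inputs.

    Per input tree an independent random taxon deletion is applied; the tree
    is then either the clean restriction of the model, a neighbor-joining
    reconstruction from a fresh simulated sequence block, or a restriction
    degraded by random NNI moves.  Clean restrictions keep the outgroup;
    NJ reconstructions use it for rooting and then drop it.
    """
    rng = _as_rng(config.seed)
    rate = config.tree_wide_rate
    if rate is None:
        rate = default_tree_rate(config.n_taxa)
    clock = yule_tree(config.n_taxa, rng)
    model = add_outgroup(deviate_rates(clock, rate, rng), config.outgroup)
    ingroup = model.leaf_labels - {config.outgroup}

    inputs: list[RootedTree] = []
    for _ in range(config.n_input_trees):
        if config.input_mode == "sequence_nj":
            block = evolve_sequences(model, config.block_length, config.gtr, rng)
            reduced = delete_taxa(model, config.deletion_ratio, rng, keep={config.outgroup})
            inputs.append(nj_tree(block.subset(reduced.leaf_labels), config.outgroup))
        else:
            reduced = delete_taxa(model, config.deletion_ratio, rng, keep={config.outgroup})
            if config.input_mode == "nni_perturb":
                reduced = nni_perturb(reduced, config.nni_moves, rng)
            inputs.append(reduced)

    covered = set().union(*(t.leaf_labels for t in inputs))
    uncovered = ingroup - covered
    if uncovered:
        logger.warning("replicate leaves %d taxa uncovered by the input trees", len(uncovered))
    return model, inputs


# ---------------------------------------------------------------------------
# combinatorics


class TreeCount(NamedTuple):
    mantissa: float
    exponent: int
    exact: int | None


def count_unrooted_trees(n: int) -> TreeCount:
    """Number (2n-5)!! of unrooted binary topologies on n leaves.

    Returns a one-decimal mantissa and decimal exponent computed by summing
    log10 of the odd factors (stable for very large n), plus the exact
    integer for n <= 500.
    """
    if n < 3:
        raise ValueError("need at least 3 leaves")
    factors = range(3, 2 * n - 4, 2)
    log10 = sum(math.log10(k) for k in factors)
    exponent = math.floor(log10)
    mantissa = round(10 ** (log10 - exponent), 1)
    if mantissa >= 10.0:
        mantissa /= 10.0
        exponent += 1
    exact = math.prod(factors) if n <= 500 else None
    return TreeCount(mantissa, exponent, exact)
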