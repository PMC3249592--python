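"""Branch-length reconciliation across input trees.

BWD averages lambda values across input trees, which is only meaningful when
their branch lengths live on a common scale.  Given a reference pairwise
distance matrix D over all taxa (e.g. corrected distances from alignments)
and a tree T with path-length matrix D_T, we estimate one multiplicative
constant c per tree and rescale T by it.  Three estimators are provided:

* alpha-trimmed mean of the ratio set C = {D(t,t') / D_T(t,t')} (robust;
  the default, with alpha = 1/3),
* least squares: c = sum(D * D_T) / sum(D_T^2), the closed-form minimizer of
  sum (D - c * D_T)^2,
* minimax: c minimizing max |D - c * D_T| (a 2-variable linear program).

Pairs with a missing reference entry or D_T = 0 are excluded from every
estimator.  When all input branch lengths were estimated under one model of
sequence evolution, reconciliation is unnecessary and should be skipped (the
benchmark pipeline skips it for simulated inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .tree import Node, RootedTree, TreeError, leaf_distance_matrix


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon distance matrix; NaN marks missing pairs."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon list")
        if not np.allclose(np.nan_to_num(v - v.T), 0.0):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def tree_distance_matrix(tree: RootedTree) -> DistanceMatrix:
    """Path-length distances D_T between all leaves of a tree."""
    order, D = leaf_distance_matrix(tree)
    return DistanceMatrix(order, D)


def _usable_pairs(ref: DistanceMatrix, tree_mat: DistanceMatrix):
    """Aligned (D, D_T) vectors over shared taxa with observed, positive D_T."""
    shared = [t for t in tree_mat.taxa if t in set(ref.taxa)]
    ridx = {t: i for i, t in enumerate(ref.taxa)}
    tidx = {t: i for i, t in enumerate(tree_mat.taxa)}
    d, dt = [], []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            a, b = shared[i], shared[j]
            rv = ref.values[ridx[a], ridx[b]]
            tv = tree_mat.values[tidx[a], tidx[b]]
            if np.isnan(rv) or np.isnan(tv) or tv <= 0.0:
                continue
            d.append(rv)
            dt.append(tv)
    if not d:
        raise TreeError("no usable taxon pairs between reference and tree matrices")
    return np.array(d), np.array(dt)


def ratio_set(ref: DistanceMatrix, tree_mat: DistanceMatrix) -> np.ndarray:
    """The multiset C of pairwise ratios D / D_T over usable pairs."""
    d, dt = _usable_pairs(ref, tree_mat)
    return d / dt


def trimmed_mean_constant(
    ref: DistanceMatrix, tree_mat: DistanceMatrix, alpha: float = 1.0 / 3.0
) -> float:
    """alpha-trimmed mean of the ratio set (floor(alpha * m) cut per side).

    Robust to up to floor(alpha * m) corrupted ratios in either tail; with
    alpha = 0 it is the plain mean.
    """
    if not 0.0 <= alpha < 0.5:
        raise ValueError("alpha must lie in [0, 0.5)")
    C = np.sort(ratio_set(ref, tree_mat))
    k = math.floor(alpha * len(C))
    trimmed = C[k : len(C) - k] if k else C
    if len(trimmed) == 0:  # pragma: no cover - impossible for alpha < 0.5
        raise TreeError("trimming removed every ratio")
    return float(trimmed.mean())


def least_squares_constant(ref: DistanceMatrix, tree_mat: DistanceMatrix) -> float:
    """c = sum(D * D_T) / sum(D_T^2), minimizing sum (D - c * D_T)^2."""
    d, dt = _usable_pairs(ref, tree_mat)
    return float(np.dot(d, dt) / np.dot(dt, dt))


def minimax_constant(ref: DistanceMatrix, tree_mat: DistanceMatrix) -> float:
    """c minimizing max |D - c * D_T| via a linear program.

    Variables (c, m): minimize m subject to -m <= d_i - c * t_i <= m.
    """
    d, dt = _usable_pairs(ref, tree_mat)
    # rows: [-t, -1] . (c, m) <= -d   and   [t, -1] . (c, m) <= d
    A = np.vstack([np.column_stack([-dt, -np.ones_like(dt)]),
                   np.column_stack([dt, -np.ones_like(dt)])])
    b = np.concatenate([-d, d])
    res = linprog(c=[0.0, 1.0], A_ub=A, b_ub=b, bounds=[(None, None), (0, None)],
                  method="highs")
    if not res.success:  # pragma: no cover - bounded feasible by construction
        raise TreeError(f"minimax LP failed: {res.message}")
    return float(res.x[0])


def apply_constant(tree: RootedTree, c: float) -> RootedTree:
    """Multiply every branch length of a tree by c > 0."""
    if c <= 0:
        raise ValueError("scaling constant must be positive")

    def scale(node: Node) -> Node:
        new = Node(node.label, None if node.length is None else node.length * c)
        for child in node.children:
            new.add_child(scale(child))
        return new

    return RootedTree(scale(tree.root))


# ---------------------------------------------------------------------------
# reference matrices from alignments


def p_distance_matrix(sequences: dict[str, np.ndarray], jukes_cantor: bool = True) -> DistanceMatrix:
    """Pairwise distances from equal-length encoded sequences.

    With ``jukes_cantor=True`` the proportion of differing sites p is
    corrected to d = -3/4 ln(1 - 4p/3); saturated pairs (p >= 3/4) are capped
    just below saturation so the correction stays finite.
    """
    taxa = sorted(sequences)
    n = len(taxa)
    D = np.zeros((n, n))
    arrs = [np.asarray(sequences[t]) for t in taxa]
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arrs[i] != arrs[j]))
            if jukes_cantor:
                p = min(p, 0.7499)
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:
                dist = p
            D[i, j] = D[j, i] = dist
    return DistanceMatrix(taxa, D)


def read_phylip_matrix(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix."""
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    taxa, rows = [], []
    pos = 1
    for _ in range(n):
        taxa.append(tokens[pos])
        rows.append([float(x) for x in tokens[pos + 1 : pos + 1 + n]])
        pos += 1 + n
    return DistanceMatrix(taxa, np.array(rows))


def write_phylip_matrix(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)}\n")
        for i, t in enumerate(matrix.taxa):
            row = " ".join(f"{v:.10g}" for v in matrix.values[i])
            fh.write(f"{t} {row}\n")
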