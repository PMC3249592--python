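# Methods notes

This note records the models implemented by `polysuper`, the defaults and
why they were chosen, and the numerical and design decisions a maintainer
would otherwise have to reverse-engineer from the code.

## Tree model and primitives

A `RootedTree` is a rooted phylogenetic tree with uniquely labeled leaves
and optional nonnegative branch lengths (expected substitutions per site).
Degree-two chains are suppressed on construction with branch lengths summed,
so path lengths between retained leaves are invariant under restriction.
Label comparison is exact byte equality.  Newick parsing is delegated to
dendropy (quoted labels and scientific-notation lengths accepted; internal
labels parsed but ignored); output uses 10 significant digits, enough for a
faithful round trip without decimal noise.  Trees whose basal trifurcation
marks an unrooted estimate can be rooted on an outgroup's pendant edge with
`root_with_outgroup`.

Zero-length branches are treated as resolved: topology is authoritative in
triplet extraction, since collapsing numerically-zero bifurcations would
make resolution depend on floating-point underflow rather than on structure.

## Build, MC, MMC

On taxon set U each input tree is restricted to its share of U and votes on
every retained leaf pair: support if the pair's lca is below the restricted
root, contradiction if it *is* the root.  A restricted tree with exactly two
shared leaves therefore counts as co-occurrence plus contradiction — it
keeps the per-edge identity `weight + n_contradict = n_cooccur` exact, at
the cost of counting an uninformative tree as a disagreement; this matters
only to MMC's edge protection and is deliberate.

Conflict resolution:

* **MC** contracts edges supported by every input tree alive at the current
  level (trees with ≥ 3 leaves in U), then deletes from the uncontracted
  graph every edge lying in at least one *global minimum cut* of the
  contracted, support-weighted graph.  Deleting the union of all minimum
  cuts — rather than an arbitrary one — is what makes the output invariant
  under input order and relabeling; ties in cut choice never arise because
  no choice is made.
* **MMC** instead contracts every *uncontradicted* edge, so no cut can
  separate a pair that no input tree disagrees with; only contradicted edges
  are cut candidates.  This yields the clade-survival guarantee (any input
  clade contradicted by no tree appears in the output), which the test suite
  asserts directly.
* An edge {a, b} lies in some global minimum cut iff the minimum a–b cut
  weight equals the global minimum (every cut separating a from b contains
  the edge).  All pairwise minimum-cut weights are read off one Gomory–Hu
  tree (computed by igraph), so one connected-component event costs n − 1
  max-flow computations instead of one per edge.  This is exact at any size;
  no approximate fallback is needed.
* If contraction merges a conflicting component into a single supervertex,
  the methods emit a polytomy over that component with a warning.  For MMC
  this is not a rare corner: with low taxon overlap and noisy inputs most
  pairs co-occur in few trees and are never contradicted, the uncontradicted
  subgraph often spans the component, and MMC degenerates to a star.  The
  MMC realized here is an edge-classification variant that satisfies the
  published clade-survival guarantee; it is not claimed to reproduce every
  tie-breaking detail of the original implementation, whose graph
  construction is not fully specified in the literature we follow.
* Everywhere else ties (component order, child order) are broken by
  lexicographically smallest leaf label, for reproducibility.

## BWD

λ is computed once from the full input trees and never recomputed on
restrictions: λ is defined from the input trees themselves, and per-level
recomputation would silently change the averaging weights as taxa drop out.
In the SAC/SAC_max sums, z ranges over U \ {x, y} (primary evidence is
undefined for non-distinct labels), and U is the component from the previous
recursion level.  The cross-tree edge rule is applied in both orientations
of the pair and requires a strict inequality λ(x, y) < λ(x, z).

The bisection threshold θ is the bottleneck of the support-weighted graph:
the minimum edge weight on a maximum spanning tree (computed by Kruskal on
descending weights).  Weights are compared as exact doubles; if all weights
are equal the whole component shatters into singletons, i.e. a polytomy.
Singleton components attach as leaves of the current node.  All supports
scale linearly in the branch lengths, so rescaling every input by a common
factor provably leaves the topology unchanged (asserted as a property test).

BWD carries no compatibility guarantee: distance signal may override
topology even on compatible inputs.  Empirically (and by construction) a
single binary input tree with positive lengths is returned unchanged, since
each recursion level's Build graph is already disconnected.

## Branch-length reconciliation

Given a reference matrix D and a tree matrix D_T, the ratio set
C = {D(t,t′)/D_T(t,t′)} is built from pairs with observed entries and
D_T > 0 (excluded pairs are counted in the log).  The α-trimmed mean drops
⌊α·|C|⌋ elements per side — symmetric floor trimming, the standard
convention — with default α = 1/3, making the estimator exact under up to
⌊α·|C|⌋ corrupted ratios per tail.  The least-squares constant has the
closed form Σ D·D_T / Σ D_T²; the minimax constant solves the two-variable
linear program min m s.t. |D − c·D_T| ≤ m (the objective is piecewise-linear
convex in c, so the LP solution is exact).  Reference matrices from
alignments default to Jukes–Cantor-corrected p-distances (raw p-distance is
available); saturated pairs are capped just below p = 3/4 so the correction
stays finite.  Only the all-distances ratio construction is implemented; the
sketchier largest-distance normalization variant has no concrete definition
to implement.  When all inputs were estimated under one model of sequence
evolution, reconciliation is a no-op and the benchmark pipeline skips it for
simulated data.

## Comparison metrics

* RF normalization uses |C₁| + |C₂| over nontrivial non-root clades
  (size ≥ 2, proper subset), which gives exactly [0, 1] and matches the
  n − 2 resolution denominator: a rooted binary tree on n leaves has n − 2
  such clades.  Two stars compare at distance 0 by continuity; the same 0/0
  convention applies to d_TR.
* The triplet comparison classifies all C(n, 3) leaf triples into
  same/diff/r1/r2/x via lca-depth matrices: of the three pairwise lca depths
  of a triple the two smallest are always equal, so the triple is resolved
  iff the maximum is unique and the maximizing pair is the cherry.  The
  enumeration is O(n³), which is fine at the few-hundred-taxon scale this
  package targets; the bins partitioning C(n, 3) is asserted, and for a
  fully resolved first tree r2 = x = 0 necessarily.
* Rooted MAST is a dynamic program over node pairs, with a maximum-weight
  assignment (scipy's Hungarian solver) matching child lists at polytomies;
  it is validated against subset brute force for n ≤ 8.
* Nonplenary supertrees are compared after restricting the model tree, so a
  two-taxon supertree scores perfect RF and triplet distances — only the
  MAST score, normalized by the *full* model leaf count, penalizes dropped
  taxa.  This asymmetry is intentional and mirrors how nonplenary methods
  must be read with caution.

## Synthetic data

The generator reproduces the structure of the classic benchmark, not any
particular empirical dataset:

* **Yule trees** from a unit-rate pure-birth process (two lineages from the
  root; after the n-th lineage one extra exponential waiting time so the
  last cherry has positive pendants).  The original study used an external
  tree simulator whose exact defaults are not recoverable; only the shape
  distribution matters downstream, and the substitution scale is set by
  `tree_wide_rate`, whose default calibrates the expected root-to-tip path
  to ≈ 0.3 substitutions/site — a realistic depth for a moderately diverged
  nuclear-gene phylogeny.
* **Rate deviation** multiplies each branch duration by a Normal(1.0, 0.5)
  variate truncated to [0.1, 2.0] (rejection sampling reproduces the
  truncation exactly) times the tree-wide rate.
* **Outgroup**: the taxon farthest from all others defines d_max; if d_max
  exceeds the runner-up taxon's maximum distance by more than 75% the
  pendant branch is shortened until the excess is exactly 75% (this reading
  of the shortening rule is isolated in one function and logged whenever it
  fires); the outgroup attaches above the root with pendant length
  1.25 × d_max.
* **Sequences** evolve under GTR+Γ+I with frequencies
  (A, C, G, T) = (0.3468, 0.3594, 0.0805, 0.2133) — the fourth value is the
  complement of the three quoted ones — exchangeabilities
  (AC, AG, AT, CG, CT) = (0.6750, 27.9597, 1.1677, 0.4547, 20.8760) with GT
  fixed to 1, Γ shape 1.1999, and invariant proportion 0.4954.  The rate
  matrix is normalized to one expected substitution per unit branch length
  at stationarity; variable-site Gamma rates are rescaled by 1/(1 − p_inv)
  so the mean site rate is 1.  Transition matrices come from the symmetric
  eigendecomposition of the reversible generator, vectorized over sites.
* **Input trees**: per input, an independent uniform deletion of
  ⌊ratio · n⌋ ingroup taxa (the outgroup is never deleted), then either the
  clean restriction of the model tree, a neighbor-joining reconstruction
  from a fresh sequence block (1000 bp up to 144 taxa, 500 bp beyond),
  or a restriction degraded by k random NNI moves.  NJ runs on
  Jukes–Cantor distances, is rooted on the outgroup and then drops it, and
  clamps the occasional negative NJ branch length to zero.  NJ stands in
  for full maximum-likelihood reconstruction to keep the pipeline
  self-contained; it is noisier than ML at the same block length, so
  absolute accuracy numbers are conservative while method *orderings* — the
  quantity of interest — are preserved.  Replicates whose input trees fail
  to cover every model taxon are flagged in the log, not rejected.

What passing tests on these data do **not** show: robustness to model
misspecification (simulation and reconstruction share the GTR family up to
the JC approximation), to alignment error (sites are generated aligned), or
to non-uniform taxon sampling; real-world inputs also require the
reconciliation step that simulated inputs legitimately skip.

## Benchmark pipeline

One row per (replicate, method, setting); per-replicate seeds are spawned
from the configuration seed, so any row is reproducible in isolation.  The
outgroup is pruned from both the supertree and the model tree before metric
computation — it exists for rooting, not for evaluation.  `Incompatible`
results from Build become status-flagged rows rather than failures.  Default
problem sizes in the shipped configurations (tens of replicates, 48–96
taxa) were chosen so a full run completes on a laptop in minutes;
`SimulationConfig` accepts the larger historical settings (144 and 524 taxa,
replicate counts of 100) unchanged.

The acceptance script reports the mean BWD–SAC supertree resolution at 75%
deletion (96 taxa, 16 input trees, 20 replicates) — the regime where
resolution separates the methods most sharply — computed from scratch at
every invocation.

## Known limitations

* MMC's edge-classification realization degenerates to polytomies in
  high-conflict, low-overlap regimes (see above).
* The triplet-distance enumeration is O(n³) and the MAST DP O((nm)·deg²);
  both are fine below ~1000 taxa but would need sparsification beyond.
* Support functions beyond SAC/SAC_max (primary, confirmed, accumulated
  primary) have no published formulas to implement and are out of scope, as
  are matrix-representation, veto-based, and super-distance-matrix supertree
  methods, which rest on external solvers.
* The Yule generator produces ultrametric durations only; empirical
  non-clocklike depth heterogeneity enters solely through the rate
  multipliers.
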