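# Methods

This note records the models and procedures `phylodraw` implements, the
choices that were genuinely open, and what the synthetic fixtures do and
do not demonstrate.

## Network model and validation

A rooted phylogenetic network is a DAG with one in-degree-0 root,
taxon-labeled leaves (a bijection), no through nodes (in-degree 1 and
out-degree 1), and leaf in-degree ≤ 1. The leaf in-degree rule is
phrased softly in parts of the literature; we enforce it as a hard
validator rule, because a multi-parent leaf breaks the backbone
construction's assumption that every network leaf is a backbone leaf.
Validation returns violation records instead of raising: capture output
and interactive edits legitimately pass through invalid states, and the
caller decides what to repair. Construction-time errors are reserved
for states that cannot be represented at all (duplicate taxon labels,
parallel edges, self-loops, dangling ids).

## Extended Newick

Tag dialects `#H<i>`, `#LGT<i>`, `#R<i>` and bare `#<i>` are accepted;
all occurrences of a tag contribute a parent edge, the occurrence with
a subtree (or the first, in text order) carries the children, and `##`
marks that parent edge as the transfer-acceptor. A branch length on a
reticulate occurrence attaches to that specific parent edge. Internal
names are kept as display labels, not taxa. Through nodes arising from
redundant parentheses are contracted at parse time (summing weights);
a labeled through node is kept, so the validator can surface it. On
writing, each reticulate node's inline occurrence is the first parent
reached in a preorder walk with children in node-id order — a purely
deterministic choice so output is stable across runs. Weights are
written with `repr`, which round-trips doubles exactly.

## Backbone tree and LSA

The lowest stable ancestor of a node — the last node on all root paths
— equals its immediate dominator, computed once for the whole network
(Cooper–Harvey–Kennedy iteration as shipped by networkx; near-linear).
The test suite cross-checks this against literal path enumeration on
small networks. The backbone re-attaches every combining reticulation
below its LSA; in the transfer view, flagged reticulations keep exactly
their acceptor edge. Every backbone edge either is a network edge or
runs from a dominator to a dominated node, so the result is always a
spanning tree regardless of processing order (the order-dependence
worry only arises if one recomputes dominators between reroutes, which
we do not). A transfer-view request on a network with unflagged
reticulations silently falls back to combining-style rerouting for
those nodes — a drawing should not fail because metadata is partial.

Backbone through nodes and unlabeled backbone leaves are kept: they
carry coordinates. Default child order sorts siblings by the smallest
taxon label in their subtree (ties by node id), giving the optimizer a
reproducible starting point.

## Coordinates

y: post-order over the backbone, i-th leaf (0-based) at y = i, internal
nodes at the mean of their children or, optionally, of their descendant
backbone leaves. 0-based indexing keeps the circular formula's range
`0 .. n−1` literal.

x (cladogram): d(v) = longest root path in the *network* (not the
backbone). The transfer adjustment enforces d(source) ≥ d(target) per
transfer edge by raising sources and re-propagating strict monotonicity
along tree and acceptor edges, iterated to a fixpoint with a pass cap of
|V|. The fixpoint exists exactly when no transfer source reaches its
target through tree/acceptor edges (a time-consistency condition); a
time-inconsistent input trips the cap and raises, which we prefer to
silently emitting a drawing that violates the documented invariant.

Late timing right-aligns all leaves at the maximum depth and assigns
every internal node min(children) − 1 in reverse topological order,
which preserves strict increase along every edge; it is defined for
cladograms only (phylogram x is dictated by branch lengths) and a
late+phylogram request is rejected.

x (phylogram): x(v) = x(parent) + ω(e) along tree/acceptor edges
(weights are required there and missing ones are an error naming the
edge); a combining reticulation sits at max(parents) + δ. δ defaults to
2% of the weighted height with a 10⁻⁶ floor — visually negligible but
strictly positive, so reticulate edges always run left-to-right. For
exactness checks, pass a dyadic δ (e.g. 1/64): with dyadic branch
lengths all coordinates are then exactly representable and
x(w) − x(v) == ω(e) holds bitwise.

Equal spacing: labeled leaves are re-assigned exact integers 0..|X|−1
in traversal order; a run of m unlabeled backbone leaves between labels
k and k+1 gets k + j/(m+1); boundary runs extend outward by the same
fractions (below 0 / above |X|−1). Relative leaf order is untouched, so
the optimizer's result and the planarity guarantee survive re-spacing.

Circular: angle = y/H·360° taken modulo 360 into [0°, 360°), with
H = backbone leaves + 1; radius = x + r₀ with r₀ = 1 drawing unit so
the root is not a degenerate point. y increases downward/clockwise,
x rightward, origin at the root.

## Displacement optimization

Objective: Σ |Δy| over reticulate edges, acceptor edges excluded;
circular variant min(|Δy|, H − |Δy|). The problem contains Minimum
Linear Arrangement (star reduction, see below) and is NP-hard, so the
optimizer is a heuristic with an exact small-instance oracle beside it.

Per-node move: at a visited node, evaluate candidate child permutations
by recomputing y globally — stale-coordinate bugs are a bigger hazard
than the O(|V|) per evaluation at the sizes this tool targets. Up to 8
children all permutations are tried; above 8, simulated annealing over
pairwise swaps with geometric cooling (defaults 1000 → 0.01, 1000
iterations per temperature step, rate 0.95; ~225 temperature steps).
Annealing is Metropolis acceptance exp(−Δ/T) with best-so-far tracking
and is deterministic per seed.

Which nodes to visit was genuinely open. Restricting to LSAs of
reticulations is cheapest, but a node whose subtree merely *contains*
the source of a reticulate edge also moves that source's y relative to
its target, so LSA-only misses improvements (measured: 8% of small
random instances land above the enumerated optimum). The default
therefore visits every multi-child node; `nodes="lsa"` remains
available. Pure per-node coordinate descent also has genuine local
minima that need a coordinated reorder at two nodes to escape, so the
descent sweeps until it stops improving (≤ 10 sweeps) and is restarted
from 8 seeded shuffles, keeping the best. With that configuration the
optimizer matched full joint enumeration on 200/200 random instances
with ≤ 7 backbone leaves and ≤ 3 reticulations. Restarts are skipped
when annealing engages (it carries its own stochastic escape and
dominates runtime) and when only one node is optimizable (a single
exhaustive enumeration is already exact). The optimizer never returns
an order worse than its input: the input order is always a candidate.

MinLA reduction: a graph G becomes a star — root over one node per
vertex, each with a pendant labeled leaf — with G's edges as reticulate
(transfer) edges and the root edges of in-degree-≥2 vertices flagged as
acceptors. Pendants make backbone leaves evenly spaced, so a leaf
order's displacement equals the MinLA cost of f = rank + 1 exactly; an
isolated vertex yields a through node (flagged by the validator,
irrelevant to the arithmetic). The reduction is validated in both
directions against n! enumeration.

## Synthetic networks

The generator grows a random binary tree by uniform edge attachment,
then adds each reticulation by subdividing an ordered pair of tree
edges (ordered by topological rank of the source, which makes
acyclicity automatic) and connecting the two new nodes. Every node
carries a simulated time (subdivisions at interval midpoints). Two
pairing policies:

- `nested` (default): any ordered pair — hybridization-style networks
  where a reticulation may connect nested lineages;
- `cross`: only edge pairs whose time intervals overlap, joined at a
  common time — time-consistent lateral transfers. This is required
  for transfer-view fixtures: without it the depth adjustment can lack
  a finite fixpoint, either through a transfer descending its own
  acceptor lineage or through two transfers straddling each other's
  lineages (both arise readily in unconstrained sampling).

Optional extras: an acceptor flag on the in-lineage parent edge of
every reticulation, and dyadic branch lengths (k/8, k = 1..16) on all
edges. Sizes used by the scripted checks follow the benchmark setup of
n = 50 taxa with h = 0.2·n = 10 reticulations, 10 replicates; smaller
batteries use n ≤ 30. No claim is made that this generator matches any
published simulator's distribution — it is a validity-guaranteed
fixture source, and results on it say nothing about inference quality
on real data, only about the layout machinery's contracts.

Fig-5-style normalized displacement divides RD by (backbone leaves −
1), the drawing's total height in leaf units; the exact normalizer in
prior art is not standardized, so the choice is recorded here.

## Rendering

SVG 1.1 text, written directly (the element set is small and flat):
tree/acceptor edges as vertical-then-horizontal two-segment paths,
reticulate and transfer edges as dashed quadratic curves, labels right
of leaves or rotated radially; circular layouts use an arc at the
parent radius plus a radial segment. The raster fixture renderer draws
only the line geometry onto a white uint8 canvas (1-px strokes via
Bresenham lines, x stretched 2× relative to the leaf spacing) and
exports label texts purely as a sidecar of boxes with fixed 6×10-px
per-character metrics — no font engine, no text pixels, which is what
lets capture tests bypass OCR entirely and stay deterministic.

## Capture

Binarize (luminance < threshold; Otsu by default, blank images are an
error) → skeletonize (topology-preserving thinning; 8-connected
foreground) → node detection → path tracing → assembly.

Node mask: endpoints are skeleton pixels with exactly one neighbor.
Junctions are pixels whose 8-neighborhood splits into ≥ 3 connected
arcs (Rutovitz crossing number) rather than pixels with ≥ 3 neighbors:
the raw count misclassifies corner pixels of bent one-pixel lines,
whose neighbors are adjacent to each other. 8-adjacent junction pixels
merge into one cluster with a centroid position. Tracing walks
degree-≤2 chains outward from clusters, terminating on node adjacency;
remaining pixels form closed loops (paths with no end clusters). Every
skeleton pixel lands in exactly one path or cluster.

Assembly places the root at the skeleton pixel nearest the requested
location (default tolerance 5 px), splitting a path — or opening a
closed loop — if it falls in an interior. Orientation is inferred by
comparing the root with the node cloud (radial if the root sits in the
central quarter of the bounding box). Paths touching the growing
component are inserted in deterministic order, directed away from the
connected side; when both ends are already connected the drawing axis
decides, falling back to insertion order, and an insertion that would
close a directed cycle is tried in reverse before the path is declared
unresolved. Self-loop paths are always unresolved (a loop cannot be
acyclic), which is exactly what a captured cycle — e.g. a triangle,
which skeletonizes to a single closed curve — produces: one unresolved
path. Sub-threshold self-loop bumps (< 4 px), a standard thinning
artifact at stroke corners, are pruned before assembly.

Labels attach to the nearest node; texts landing on out-degree-0 nodes
become taxa, others become display annotations. OCR is deliberately a
pluggable provider: the shipped provider is the fixture sidecar, so no
OCR engine is required anywhere in the test path, and OCR accuracy is
out of scope.

Post-processing mirrors manual clean-up: through-node contraction
(weights summed when present; a contraction that would create a
parallel edge is skipped), in-2/out-2 crossing replacement (in/out
strokes paired by collinearity from node positions, symmetric ties
broken toward the smaller node id), and node merging (labels united,
two taxa in one merge rejected to keep λ bijective).

What the capture fixtures show — and do not: round-trips succeed on
clean, self-rendered rasters with known label boxes; they say nothing
about scanned figures, anti-aliased or colored artwork, overlapping
labels, or OCR quality. Those need preprocessing and a real OCR
provider.

## Numerical and determinism notes

Exact comparisons are reserved for quantities that are exact by
construction (integer depths, dyadic phylogram arithmetic, leaf
integers after equal spacing); everything else uses small absolute
tolerances (1e-9 .. 1e-12) only to absorb float noise in means. All
stochastic components (generator, annealing, restarts) take explicit
seeds and derive per-node sub-seeds deterministically; repeated runs
are byte-identical. Crossing checks exploit that all tree-edge
segments are axis-aligned: any contact between segments of
node-disjoint edges counts as a crossing.

## Known limitations

- The displacement optimizer is a heuristic; beyond the enumerable
  regime its gap to the optimum is unquantified (NP-hardness applies).
- The pre-order + multi-start scheme can still, in principle, miss
  optima needing simultaneous reorders at ≥ 3 nodes.
- Transfer-depth adjustment requires time-consistent inputs; real
  networks with inconsistent transfers raise rather than render in the
  transfer cladogram (the combining view always works).
- Capture assumes thin dark lines on white, non-overlapping labels,
  and a nearby root click; curves are traced topologically, but two
  strokes crossing in the figure are captured as a 4-degree node that
  the user must split with the crossing-replacement operation.
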