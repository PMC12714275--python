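# phylodraw

Layout, optimization and figure-capture of **rooted phylogenetic
networks** — trees extended with reticulate nodes that model
hybridization, horizontal gene transfer or reassortment.

Rooted networks are produced routinely by network-inference tools and
exchanged in extended Newick, but drawing them well is harder than
drawing trees: a network need not be planar, so some reticulate edges
must cross. `phylodraw` computes left-to-right and circular drawings in
which **tree edges never cross** and the visual clutter of reticulate
edges is minimized, and it can recover a network's topology from a
published figure when no machine-readable form is available.

Who is it for: anyone who needs to render, re-layout, convert or
digitize rooted phylogenetic networks from Python or the shell —
the same audience served by tree viewers, extended to networks.

## The model

A rooted phylogenetic network `N = (V, E, ρ, λ)` on taxa `X` is a DAG
with a unique root `ρ` and a bijection `λ` between `X` and the leaves.
A node with in-degree ≥ 2 is *reticulate*; an edge is classified by its
target. In the *combining* view (hybridization) all in-edges of a
reticulation are drawn alike; in the *transfer* view (HGT) one in-edge
is the designated *transfer-acceptor* (written `##` in extended Newick)
and is drawn as part of the main lineage, the rest as transfer arcs.

Coordinates come from a spanning **backbone tree** `B`: each reticulate
node is re-attached below its *lowest stable ancestor* (the last node on
every root path — its immediate dominator), or, in the transfer view,
kept on its acceptor edge. A post-order traversal of `B` under a child
order `O` gives `y` (leaves at 0, 1, 2, …; internal nodes averaged), and
`x` is the depth `d(v)` (cladogram) or the accumulated branch length
(phylogram). The quality of the drawing is its **reticulate
displacement**

```
RD(K(N,B,O)) = Σ_{(v,w) ∈ R} |y(v) − y(w)|,
```

summed over reticulate edges `R` (acceptor edges excluded); the circular
variant wraps each term modulo `H = |leaves(B)| + 1`. Minimizing RD over
child orders is NP-hard (it contains Minimum Linear Arrangement), so the
optimizer walks `B` in pre-order and, per node, tries all child
permutations (≤ 8 children) or simulated annealing (start T = 1000,
end T = 0.01, 1000 iterations per step, cooling 0.95), inside a
deterministic multi-start descent.

The capture pipeline binarizes a dark-on-white figure, thins it to a
one-pixel skeleton, detects endpoints and branch points with a
neighborhood mask, flood-fills the skeleton into paths, drops paths
hidden inside label boxes, and grows a rooted network outward from a
user-chosen root location, rejecting any stroke whose insertion would
create a directed cycle.

## Worked example

```python
import phylodraw as pd

net = pd.parse_extended_newick("((a,(b)#H1),(##H1,c));")[0]
print(len(net.reticulate_nodes()), sorted(net.taxa))
# 1 ['a', 'b', 'c']

lr = pd.compute_layout(net, view="transfer", style="cladogram", seed=0)
print(lr.displacement, lr.H)
# 1.0 4
print({t: lr.xy[v] for t, v in sorted(net.taxa.items())})
# {'a': (3.0, 0.0), 'b': (3.0, 1.0), 'c': (2.0, 2.0)}

svg = pd.render_svg(net, lr)          # SVG 1.1 text, ready to save
```

The displacement `1.0` says the single transfer arc spans one leaf row
(its endpoints sit on adjacent levels — the minimum possible here, since
the arc connects the lineages of two distinct leaves), and `H = 4` is
the circular-layout modulus (3 backbone leaves + 1). Each taxon's
`(x, y)` places it at its depth column and leaf row; leaf `a` sits at
depth 3 rather than 2 because the transfer-view adjustment lifts the
transfer source to its target's level and pushes the source's
descendants along.

From the shell:

```sh
phylodraw simulate --n 20 --h 4 --seed 1 -o net.nwk
phylodraw layout net.nwk --view combining --style cladogram -o net.svg
# stderr: displacement=17.9635 normalized=0.94545 seed=0 sa=(1000.0,0.01,1000,0.95)
phylodraw capture fig.png --root 10,200 --labels boxes.tsv -o captured.nwk
```

The `examples/` directory holds one short narrative script per
capability; each prints the numbers it computes and what they mean.

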