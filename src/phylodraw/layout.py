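"""Coordinate assignment for rooted network drawings.

Drawings are left-to-right: the root sits at x = 0 and x grows toward the
leaves.  The y-coordinate of every node comes from a post-order traversal
of the backbone tree — the i-th leaf visited gets y = i (0-based) and an
internal node gets the mean of its children (or, optionally, of all its
backbone-descendant leaves).  The x-coordinate is the node depth for
cladograms (maximum number of edges on any root path), or the accumulated
branch length for phylograms.  Tree edges are drawn as two-segment
orthogonal paths from (x(v), y(v)) via (x(v), y(w)) to (x(w), y(w));
reticulate edges are drawn as curves and are the only edges allowed to
cross anything.

A *late* cladogram right-aligns the leaves and pushes every internal node
as far toward the leaves as the edge directions allow; the default *early*
cladogram keeps nodes as close to the root as possible.  The transfer view
additionally lifts the source of every transfer edge to at least the depth
of its target so that transfers can be drawn horizontally.  A circular
drawing reinterprets y as an angle (modulo H = backbone leaves + 1) and
x + r0 as a radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Tuple

from .backbone import BackboneTree, View, build_backbone
from .network import Edge, EdgeKind, PhyloNetwork, classify_edge

AveragingMode = Literal["children_mean", "descendant_leaf_mean"]
Style = Literal["cladogram", "phylogram"]
Timing = Literal["early", "late"]


@dataclass
class LayoutResult:
    """Node coordinates plus the metadata needed to render the drawing."""

    xy: Dict[int, Tuple[float, float]]
    view: View = "combining"
    style: Style = "cladogram"
    timing: Timing = "early"
    H: int = 0
    circular: Optional[Dict[int, Tuple[float, float]]] = None  # node -> (radius, angle deg)
    backbone: Optional[BackboneTree] = None
    displacement: Optional[float] = None


def assign_y(b: BackboneTree, mode: AveragingMode = "children_mean") -> Dict[int, float]:
    """Post-order y assignment: leaves 0,1,2,...; internals by averaging.

    This sits in the optimizer's inner loop, hence the flat reversed
    pre-order formulation instead of a recursive traversal.
    """
    children = b.children
    order: List[int] = []
    stack = [b.root]
    pop = stack.pop
    append = order.append
    while stack:
        v = pop()
        append(v)
        stack.extend(children[v])
    y: Dict[int, float] = {}
    i = 0
    if mode == "children_mean":
        for v in reversed(order):
            kids = children[v]
            if kids:
                y[v] = sum(y[w] for w in kids) / len(kids)
            else:
                y[v] = float(i)
                i += 1
    else:
        leaf_sum: Dict[int, float] = {}
        leaf_cnt: Dict[int, int] = {}
        for v in reversed(order):
            kids = children[v]
            if kids:
                leaf_sum[v] = sum(leaf_sum[w] for w in kids)
                leaf_cnt[v] = sum(leaf_cnt[w] for w in kids)
                y[v] = leaf_sum[v] / leaf_cnt[v]
            else:
                y[v] = float(i)
                i += 1
                leaf_sum[v], leaf_cnt[v] = y[v], 1
    return y


def compute_depths(net: PhyloNetwork) -> Dict[int, int]:
    """d(v) = maximum number of edges on any directed root-to-v path."""
    d: Dict[int, int] = {net.root: 0}
    for v in net.topological_order():
        if v == net.root:
            continue
        d[v] = 1 + max(d[u] for u in net.parents(v))
    return d


def adjust_transfer_depths(net: PhyloNetwork, d: Dict[int, int],
                           max_passes: Optional[int] = None) -> Dict[int, int]:
    """Lift transfer-edge sources to the depth of their targets.

    For every transfer edge (v, w) with d(v) < d(w), set d(v) := d(w) and
    restore d(child) > d(parent) along tree and transfer-acceptor edges by
    propagating the increase toward the leaves.  Full passes repeat until
    a fixpoint, because transfer edges can influence one another.  When a
    transfer runs down its own acceptor lineage the constraint system has
    no finite fixpoint; the pass cap (default |V|) then trips and an error
    is raised rather than looping forever.
    """
    d = dict(d)
    transfer = [e for e in net.edges
                if classify_edge(net, e) is EdgeKind.TRANSFER]
    if not transfer:
        return d
    prop_edges = [e for e in net.edges
                  if classify_edge(net, e) in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR)]
    order = net.topological_order()
    pos = {v: i for i, v in enumerate(order)}
    prop_edges.sort(key=lambda e: pos[e[0]])
    cap = max_passes if max_passes is not None else max(len(net.nodes), 4)
    for _ in range(cap):
        changed = False
        for v, w in transfer:
            if d[v] < d[w]:
                d[v] = d[w]
                changed = True
        for u, v in prop_edges:  # topological: one sweep restores monotony
            if d[v] <= d[u]:
                d[v] = d[u] + 1
                changed = True
        if not changed:
            return d
    raise RuntimeError(
        "transfer depth adjustment did not reach a fixpoint: a transfer "
        "edge descends its own acceptor lineage (time-inconsistent network)")


def assign_x_phylogram(net: PhyloNetwork, delta: Optional[float] = None) -> Dict[int, float]:
    """Weighted x-coordinates: x(v) = x(parent) + branch length.

    Every tree and transfer-acceptor edge must carry a non-negative weight.
    A combining reticulation is placed just right of its rightmost parent,
    x(v) = max over parents + delta, so that reticulate edges always run
    left-to-right.  ``delta`` defaults to 2% of the weighted height of the
    tree part (with a small floor), a visually negligible offset.
    """
    kinds = {e: classify_edge(net, e) for e in net.edges}
    for e, k in kinds.items():
        if k in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR) and e not in net.weights:
            raise ValueError(f"missing branch length on edge {e}")

    order = net.topological_order()
    if delta is None:
        span: Dict[int, float] = {net.root: 0.0}
        for v in order:
            for u, w in net.out_edges(v):
                if kinds[(u, w)] in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR):
                    span[w] = max(span.get(w, 0.0),
                                  span.get(u, 0.0) + net.weights[(u, w)])
        delta = max(0.02 * max(span.values(), default=0.0), 1e-6)

    x: Dict[int, float] = {net.root: 0.0}
    for v in order:
        if v == net.root:
            continue
        acc = [e for e in net.in_edges(v)
               if kinds[e] in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR)]
        if acc:
            u = acc[0][0]
            x[v] = x[u] + net.weights[acc[0]]
        else:  # combining reticulation
            x[v] = max(x[u] for u in net.parents(v)) + delta
    return x


def apply_late_layout(net: PhyloNetwork, x: Dict[int, float]) -> Dict[int, float]:
    """Push internal nodes toward the leaves (cladograms only).

    Leaves are right-aligned at the maximal depth; every internal node
    then takes min over its out-neighbours minus one, processed in
    reverse topological order, which keeps x strictly increasing along
    every edge.
    """
    leaves = net.leaves()
    top = max((x[v] for v in leaves), default=0.0)
    out: Dict[int, float] = {}
    for v in reversed(net.topological_order()):
        if net.out_degree(v) == 0:
            out[v] = top
        else:
            out[v] = min(out[w] for w in net.children(v)) - 1
    return out


def equalize_leaf_spacing(b: BackboneTree, net: PhyloNetwork,
                          mode: AveragingMode = "children_mean") -> Dict[int, float]:
    """Re-space leaves so labeled leaves sit at exact integers 0..|X|-1.

    The post-order traversal is repeated with the (optimized) child order
    fixed; a maximal run of m unlabeled backbone leaves between labeled
    neighbours at k and k+1 receives k + j/(m+1); runs before the first or
    after the last labeled leaf extend outward by the same fractions.
    Internal y values are then recomputed with the chosen averaging mode.
    """
    labeled = set(net.taxa.values())
    seq = [v for v in b.postorder() if not b.children[v]]
    n_labeled = sum(1 for v in seq if v in labeled)
    if n_labeled == 0:
        return assign_y(b, mode)

    yleaf: Dict[int, float] = {}
    idx = 0
    positions_labeled = [i for i, v in enumerate(seq) if v in labeled]
    first, last = positions_labeled[0], positions_labeled[-1]
    for i, v in enumerate(seq):
        if v in labeled:
            yleaf[v] = float(idx)
            idx += 1
    # interpolate runs of unlabeled leaves
    i = 0
    while i < len(seq):
        if seq[i] in labeled:
            i += 1
            continue
        j = i
        while j < len(seq) and seq[j] not in labeled:
            j += 1
        run = seq[i:j]
        m = len(run)
        if i == 0:  # before the first labeled leaf
            base = yleaf[seq[first]]
            for k, v in enumerate(run):
                yleaf[v] = base - (m - k) / (m + 1)
        elif j == len(seq):  # after the last labeled leaf
            base = yleaf[seq[last]]
            for k, v in enumerate(run):
                yleaf[v] = base + (k + 1) / (m + 1)
        else:
            lo = yleaf[seq[i - 1]]
            for k, v in enumerate(run):
                yleaf[v] = lo + (k + 1) / (m + 1)
        i = j

    y: Dict[int, float] = {}
    leaf_sum: Dict[int, float] = {}
    leaf_cnt: Dict[int, int] = {}
    for v in b.postorder():
        kids = b.children[v]
        if not kids:
            y[v] = yleaf[v]
            leaf_sum[v], leaf_cnt[v] = y[v], 1
        elif mode == "children_mean":
            y[v] = sum(y[w] for w in kids) / len(kids)
        else:
            leaf_sum[v] = sum(leaf_sum[w] for w in kids)
            leaf_cnt[v] = sum(leaf_cnt[w] for w in kids)
            y[v] = leaf_sum[v] / leaf_cnt[v]
    return y


def to_circular(lr: LayoutResult, r0: float = 1.0) -> LayoutResult:
    """Wrap a linear layout onto a circle.

    angle(v) = y(v) / H * 360 degrees (taken modulo 360 into [0, 360)),
    radius(v) = x(v) + r0; the root offset r0 keeps the root off the
    degenerate centre point.
    """
    if lr.H <= 0:
        raise ValueError("H must be positive for a circular layout")
    circular = {}
    for v, (x, yy) in lr.xy.items():
        angle = (yy / lr.H * 360.0) % 360.0
        circular[v] = (x + r0, angle)
    return LayoutResult(xy=dict(lr.xy), view=lr.view, style=lr.style,
                        timing=lr.timing, H=lr.H, circular=circular,
                        backbone=lr.backbone, displacement=lr.displacement)


# -- top-level pipeline ------------------------------------------------

def compute_layout(net: PhyloNetwork,
                   view: View = "combining",
                   style: Style = "cladogram",
                   timing: Timing = "early",
                   mode: AveragingMode = "children_mean",
                   optimize: bool = True,
                   cost: Literal["linear", "circular"] = "linear",
                   equal_spacing: bool = True,
                   circular: bool = False,
                   delta: Optional[float] = None,
                   r0: float = 1.0,
                   sa=None,
                   seed: int = 0) -> LayoutResult:
    """Full layout pipeline: backbone, order optimization, coordinates.

    This is the one-call entry point mirroring what the command line
    offers; the individual steps remain available for finer control.
    """
    from .optimize import SAConfig, optimize_child_orders, reticulate_displacement

    if style == "phylogram" and timing == "late":
        raise ValueError("late layout is defined for cladograms only "
                         "(phylogram x is determined by branch lengths)")

    b = build_backbone(net, view=view)
    if optimize and net.reticulate_nodes():
        sa = sa or SAConfig(seed=seed)
        b = optimize_child_orders(net, b, cost=cost, sa=sa, mode=mode)

    if equal_spacing:
        y = equalize_leaf_spacing(b, net, mode=mode)
    else:
        y = assign_y(b, mode=mode)

    if style == "cladogram":
        d = compute_depths(net)
        if view == "transfer":
            d = adjust_transfer_depths(net, d)
        x = {v: float(dv) for v, dv in d.items()}
        if timing == "late":
            x = apply_late_layout(net, x)
    else:
        x = assign_x_phylogram(net, delta=delta)

    xy = {v: (x[v], y[v]) for v in net.nodes}
    rd = reticulate_displacement(y, net.reticulate_edges())
    lr = LayoutResult(xy=xy, view=view, style=style, timing=timing,
                      H=b.H, backbone=b, displacement=rd)
    if circular:
        lr = to_circular(lr, r0=r0)
    return lr


# -- crossing checks ---------------------------------------------------

def tree_edge_segments(net: PhyloNetwork, lr: LayoutResult,
                       include_acceptors: bool = True):
    """Two-segment orthogonal polylines for tree (and acceptor) edges."""
    segs = []
    for e in net.edges:
        k = classify_edge(net, e)
        if k is EdgeKind.TREE or (include_acceptors and k is EdgeKind.TRANSFER_ACCEPTOR):
            v, w = e
            xv, yv = lr.xy[v]
            xw, yw = lr.xy[w]
            segs.append((e, ((xv, yv), (xv, yw))))
            segs.append((e, ((xv, yw), (xw, yw))))
    return segs


def count_crossings(segments) -> int:
    """Count intersecting segment pairs between edges sharing no endpoint.

    Segments are axis-aligned (vertical or horizontal); any contact —
    transversal crossing, touching, or collinear overlap — between the
    polylines of two node-disjoint edges counts as a crossing.
    """
    n = 0
    for i in range(len(segments)):
        ei, si = segments[i]
        for j in range(i + 1, len(segments)):
            ej, sj = segments[j]
            if set(ei) & set(ej):
                continue
            if _segments_touch(si, sj):
                n += 1
    return n


def _segments_touch(s1, s2, eps: float = 1e-9) -> bool:
    (x1, y1), (x2, y2) = s1
    (x3, y3), (x4, y4) = s2
    v1 = abs(x1 - x2) <= eps
    v2 = abs(x3 - x4) <= eps
    if v1 and v2:
        return abs(x1 - x3) <= eps and _overlap(y1, y2, y3, y4, eps)
    if not v1 and not v2:
        return abs(y1 - y3) <= eps and _overlap(x1, x2, x3, x4, eps)
    if v1:  # s1 vertical, s2 horizontal
        return (min(x3, x4) - eps <= x1 <= max(x3, x4) + eps
                and min(y1, y2) - eps <= y3 <= max(y1, y2) + eps)
    return _segments_touch(s2, s1, eps)


def _overlap(a1, a2, b1, b2, eps) -> bool:
    lo = max(min(a1, a2), min(b1, b2))
    hi = min(max(a1, a2), max(b1, b2))
    return hi - lo > -eps
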