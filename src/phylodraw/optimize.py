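"""Reticulate-displacement minimization over backbone child orders.

The displacement of a left-to-right drawing is the sum over reticulate
edges (transfer-acceptor edges excluded) of |y(source) - y(target)|; the
circular variant wraps differences modulo H (backbone leaves + 1).  The
objective depends only on the child orders of the backbone tree, and
minimizing it is NP-hard: a Minimum Linear Arrangement instance G embeds
as a star network whose reticulate displacement equals the MinLA cost
(:func:`minla_to_network`), and that reduction also serves as a two-way
correctness oracle in the test suite.

The heuristic walks the backbone in pre-order and, at each visited node,
seeks the child permutation minimizing the global displacement (candidate
orders are evaluated by recomputing y from scratch — network sizes make
this affordable and it avoids stale-coordinate bugs).  Up to eight
children all permutations are tried; beyond that, simulated annealing
over pairwise child swaps takes over.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Literal, Optional, Sequence, Set, Tuple

from .backbone import BackboneTree, build_backbone
from .layout import AveragingMode, assign_y
from .network import Edge, PhyloNetwork

Cost = Literal["linear", "circular"]

#: beyond this many children the exhaustive branch yields to annealing
EXHAUSTIVE_THRESHOLD = 8


@dataclass
class SAConfig:
    """Simulated-annealing schedule (geometric cooling)."""

    start_temperature: float = 1000.0
    end_temperature: float = 0.01
    iterations_per_step: int = 1000
    cooling_rate: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_rate < 1.0):
            raise ValueError("cooling_rate must lie in (0, 1)")
        if not (0.0 < self.end_temperature < self.start_temperature):
            raise ValueError("need 0 < end_temperature < start_temperature")


def reticulate_displacement(y: Dict[int, float], edges: Iterable[Edge]) -> float:
    """Sum of |y(v) - y(w)| over the given reticulate edges."""
    return sum(abs(y[v] - y[w]) for v, w in edges)


def circular_displacement(y: Dict[int, float], edges: Iterable[Edge],
                          H: float) -> float:
    """Wrap-around displacement: per edge min(|dy|, H - |dy|)."""
    if H <= 0:
        raise ValueError("H must be positive")
    total = 0.0
    for v, w in edges:
        dy = abs(y[v] - y[w])
        total += min(dy, H - dy)
    return total


def displacement_of(net: PhyloNetwork, b: BackboneTree,
                    cost: Cost = "linear",
                    mode: AveragingMode = "children_mean") -> float:
    """Objective value of the current child order of ``b``."""
    y = assign_y(b, mode=mode)
    R = net.reticulate_edges()
    if cost == "circular":
        return circular_displacement(y, R, b.H)
    return reticulate_displacement(y, R)


def simulated_annealing_order(children: Sequence[int],
                              cost_fn: Callable[[Sequence[int]], float],
                              sa: SAConfig) -> List[int]:
    """Anneal over pairwise swaps; returns the best order ever seen.

    Metropolis acceptance exp(-dcost/T) with geometric cooling by
    ``cooling_rate`` after each block of ``iterations_per_step`` moves,
    until the temperature drops below ``end_temperature``.  Deterministic
    for a fixed seed.
    """
    if len(children) < 2:
        return list(children)
    rng = random.Random(sa.seed)
    cur = list(children)
    cur_cost = cost_fn(cur)
    best, best_cost = list(cur), cur_cost
    n = len(cur)
    T = sa.start_temperature
    while T >= sa.end_temperature:
        for _ in range(sa.iterations_per_step):
            i = rng.randrange(n)
            j = rng.randrange(n - 1)
            if j >= i:
                j += 1
            cur[i], cur[j] = cur[j], cur[i]
            new_cost = cost_fn(cur)
            delta = new_cost - cur_cost
            if delta <= 0 or rng.random() < math.exp(-delta / T):
                cur_cost = new_cost
                if new_cost < best_cost:
                    best_cost = new_cost
                    best = list(cur)
            else:
                cur[i], cur[j] = cur[j], cur[i]
        T *= sa.cooling_rate
    return best


def lsa_target_nodes(net: PhyloNetwork, b: BackboneTree) -> Set[int]:
    """Nodes that are the lowest stable ancestor of some reticulation."""
    from .backbone import _dominators

    if not net.reticulate_nodes():
        return set()
    doms = _dominators(net)
    return {doms[v] for v in net.reticulate_nodes()}


def optimize_child_orders(net: PhyloNetwork, b: BackboneTree,
                          cost: Cost = "linear",
                          sa: Optional[SAConfig] = None,
                          mode: AveragingMode = "children_mean",
                          nodes: Literal["all", "lsa"] = "all",
                          exhaustive_threshold: int = EXHAUSTIVE_THRESHOLD,
                          repeats: int = 10,
                          restarts: int = 8) -> BackboneTree:
    """Multi-start pre-order child-order optimization; never worsens.

    ``nodes="all"`` (default) visits every node with two or more backbone
    children; ``nodes="lsa"`` restricts the walk to lowest stable
    ancestors of reticulations.  The restricted walk is cheaper but can
    miss improvements at nodes that merely contain the source of a
    reticulate edge somewhere in their subtree, so the full walk is the
    default.

    The pre-order pass repeats until it stops improving (at most
    ``repeats`` sweeps), and the whole descent is re-run from
    ``restarts - 1`` additional shuffled starting orders (coordinate
    descent over per-node permutations has genuine local minima that need
    a coordinated reorder at two nodes to escape; multi-start is the
    standard remedy).  When some node exceeds the exhaustive threshold
    the annealing branch — which carries its own stochastic escape —
    handles it and the extra restarts are skipped.  The input order is
    always among the candidates, so the result is never worse.
    Deterministic for a fixed ``sa.seed``.
    """
    sa = sa or SAConfig()
    R = net.reticulate_edges()
    if not R:
        return b.copy()
    H = b.H
    targets_of = {
        "lsa": lambda: {v for v in lsa_target_nodes(net, b)
                        if len(b.children[v]) >= 2},
        "all": lambda: {v for v in b.children if len(b.children[v]) >= 2},
    }
    targets = targets_of[nodes]()
    needs_sa = any(len(b.children[v]) > exhaustive_threshold for v in targets)
    if needs_sa:
        restarts = 1
    elif len(targets) == 1:
        # a single exhaustively-enumerated node is already globally exact
        restarts, repeats = 1, 1

    def descend(bb: BackboneTree) -> Tuple[float, BackboneTree]:
        def objective() -> float:
            y = assign_y(bb, mode=mode)
            if cost == "circular":
                return circular_displacement(y, R, H)
            return reticulate_displacement(y, R)

        for _ in range(max(1, repeats)):
            pass_start = objective()
            for v in bb.preorder():
                if v not in targets or len(bb.children[v]) < 2:
                    continue
                kids = bb.children[v]
                if len(kids) <= exhaustive_threshold:
                    best_cost, best = None, None
                    for perm in itertools.permutations(sorted(kids)):
                        bb.children[v] = list(perm)
                        c = objective()
                        if best_cost is None or c < best_cost:
                            best_cost, best = c, list(perm)
                    bb.children[v] = best
                else:
                    def cost_fn(order: Sequence[int]) -> float:
                        bb.children[v] = list(order)
                        return objective()

                    node_sa = SAConfig(sa.start_temperature, sa.end_temperature,
                                       sa.iterations_per_step, sa.cooling_rate,
                                       seed=(sa.seed * 1000003 + v) % (2 ** 31))
                    bb.children[v] = simulated_annealing_order(
                        list(kids), cost_fn, node_sa)
            if objective() >= pass_start - 1e-12:
                break
        return objective(), bb

    best_cost, best_b = descend(b.copy())
    rng = random.Random(sa.seed ^ 0x5EED)
    for _ in range(max(1, restarts) - 1):
        bb = b.copy()
        for v in sorted(targets):
            rng.shuffle(bb.children[v])
        c, bb = descend(bb)
        if c < best_cost - 1e-12:
            best_cost, best_b = c, bb
    return best_b


# -- MinLA reduction ---------------------------------------------------

@dataclass
class MinLAInstance:
    """Minimum Linear Arrangement: place vertices at 1..n minimizing
    the summed absolute endpoint distance over undirected edges."""

    vertices: List
    edges: Set[frozenset]

    def cost(self, f: Dict) -> float:
        assert sorted(f.values()) == list(range(1, len(self.vertices) + 1))
        return sum(abs(f[u] - f[v]) for u, v in map(sorted, self.edges))


def minla_brute_force(g: MinLAInstance) -> float:
    """Exact MinLA optimum by enumerating all n! arrangements."""
    verts = sorted(g.vertices)
    index = {u: i for i, u in enumerate(verts)}
    pairs = [(index[u], index[v]) for u, v in map(sorted, g.edges)]
    if not pairs:
        return 0.0
    best = math.inf
    for perm in itertools.permutations(range(1, len(verts) + 1)):
        c = 0
        for i, j in pairs:
            c += abs(perm[i] - perm[j])
            if c >= best:
                break
        if c < best:
            best = c
    return float(best)


def minla_to_network(g: MinLAInstance) -> Tuple[PhyloNetwork, BackboneTree]:
    """Embed a MinLA instance as a star-shaped transfer network.

    The root gets one child per MinLA vertex and every vertex a pendant
    labeled leaf, so backbone leaves are evenly spaced and the y of a
    vertex equals its leaf rank.  Each undirected MinLA edge becomes one
    reticulate (transfer) edge, oriented low-id to high-id; the root edge
    of any vertex with incoming reticulate edges is flagged as the
    transfer-acceptor, so the designated reticulate-edge set is exactly
    the original edge set and the reticulate displacement of a leaf order
    equals the MinLA cost of the arrangement f = rank + 1.  (An isolated
    MinLA vertex becomes a through node; this does not affect the
    displacement arithmetic.)
    """
    net = PhyloNetwork()
    root = net.add_node()
    net.root = root
    vmap: Dict = {}
    verts = sorted(g.vertices)
    for u in verts:
        node = net.add_node()
        vmap[u] = node
        net.add_edge(root, node)
        leaf = net.add_node()
        net.add_edge(node, leaf)
        net.add_taxon(str(u), leaf)
    for e in sorted(tuple(sorted(p)) for p in g.edges):
        u, v = e
        net.add_edge(vmap[u], vmap[v])
    for u in verts:
        if net.in_degree(vmap[u]) >= 2:
            net.acceptor_flags.add((root, vmap[u]))
    return net, build_backbone(net, view="transfer")


# -- exhaustive oracle over joint child orders -------------------------

def exhaustive_min_displacement(net: PhyloNetwork, b: BackboneTree,
                                cost: Cost = "linear",
                                mode: AveragingMode = "children_mean",
                                limit: int = 2_000_000) -> float:
    """Global optimum by enumerating ALL joint child orders of ``b``.

    Exponential; intended as the correctness oracle for the heuristic on
    small instances.  ``limit`` bounds the number of combinations.
    """
    b = b.copy()
    R = net.reticulate_edges()
    if not R:
        return 0.0
    multi = [v for v in b.children if len(b.children[v]) >= 2]
    total = 1
    for v in multi:
        total *= math.factorial(len(b.children[v]))
        if total > limit:
            raise ValueError(f"joint enumeration too large (> {limit})")
    H = b.H
    best = math.inf
    perm_lists = [list(itertools.permutations(b.children[v])) for v in multi]
    for combo in itertools.product(*perm_lists):
        for v, order in zip(multi, combo):
            b.children[v] = list(order)
        y = assign_y(b, mode=mode)
        c = (circular_displacement(y, R, H) if cost == "circular"
             else reticulate_displacement(y, R))
        if c < best:
            best = c
    return best
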