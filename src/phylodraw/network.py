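"""Rooted phylogenetic networks.

A rooted phylogenetic network on a taxon set ``X`` is a directed acyclic
graph with a single root (the unique node of in-degree 0), whose leaves
(nodes of out-degree 0) are in bijection with ``X``.  Nodes of in-degree
at least two are *reticulate* nodes and model events such as hybridization
or horizontal gene transfer; all other nodes are *tree* nodes.  Edges are
classified by their target: an edge into a tree node is a *tree edge*, an
edge into a reticulate node is a *reticulate edge*.  When exactly one
incoming edge of a reticulate node is designated as the *transfer-acceptor*
edge, the node is a *transfer* node: the acceptor edge represents the main
lineage and the remaining incoming edges are *transfer* edges.

Structural soundness (ids resolve, no parallel edges, taxon labels unique)
is enforced at construction time; the biological well-formedness rules
(acyclicity, single root, taxon/leaf bijection, no through nodes, leaf
in-degree, acceptor-flag placement) are checked by :func:`validate_network`,
which reports violations as data rather than raising, so that partially
captured or hand-edited networks can be inspected and repaired.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx

Edge = Tuple[int, int]


class NodeKind(Enum):
    TREE = "tree"
    RETICULATE = "reticulate"


class EdgeKind(Enum):
    TREE = "tree"
    RETICULATE = "reticulate"
    TRANSFER_ACCEPTOR = "transfer_acceptor"
    TRANSFER = "transfer"


@dataclass(frozen=True)
class Violation:
    """One broken well-formedness rule, naming the offending ids."""

    rule: str
    nodes: Tuple[int, ...] = ()
    edges: Tuple[Edge, ...] = ()
    message: str = ""


class PhyloNetwork:
    """Mutable rooted phylogenetic network.

    Node ids are opaque integers assigned at construction.  Taxon labels
    are arbitrary non-empty strings, mapped bijectively onto leaves;
    duplicate labels are rejected immediately.  Edge weights (branch
    lengths) are a partial map and default to absent; cladogram code never
    reads them.  Parallel edges and self-loops are rejected.
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()
        self._next_id = 0
        self.root: Optional[int] = None
        #: taxon label -> leaf node id
        self.taxa: Dict[str, int] = {}
        #: edge -> non-negative branch length (partial)
        self.weights: Dict[Edge, float] = {}
        #: edges designated as transfer-acceptor
        self.acceptor_flags: Set[Edge] = set()
        #: optional display names for internal nodes (not taxa)
        self.display_labels: Dict[int, str] = {}

    # -- construction -------------------------------------------------

    def add_node(self) -> int:
        v = self._next_id
        self._next_id += 1
        self._g.add_node(v)
        return v

    def add_edge(self, u: int, v: int, weight: Optional[float] = None,
                 acceptor: bool = False) -> Edge:
        self._check_node(u)
        self._check_node(v)
        if u == v:
            raise ValueError(f"self-loop on node {u} rejected")
        if self._g.has_edge(u, v):
            raise ValueError(f"parallel edge ({u}, {v}) rejected")
        self._g.add_edge(u, v)
        if weight is not None:
            if weight < 0:
                raise ValueError(f"negative weight on edge ({u}, {v})")
            self.weights[(u, v)] = float(weight)
        if acceptor:
            self.acceptor_flags.add((u, v))
        return (u, v)

    def remove_edge(self, u: int, v: int) -> None:
        self._g.remove_edge(u, v)
        self.weights.pop((u, v), None)
        self.acceptor_flags.discard((u, v))

    def remove_node(self, v: int) -> None:
        for e in list(self.in_edges(v)) + list(self.out_edges(v)):
            self.remove_edge(*e)
        self._g.remove_node(v)
        self.display_labels.pop(v, None)
        for label, node in list(self.taxa.items()):
            if node == v:
                del self.taxa[label]

    def add_taxon(self, label: str, node: int) -> None:
        self._check_node(node)
        if not label:
            raise ValueError("empty taxon label")
        if label in self.taxa:
            raise ValueError(f"duplicate taxon label {label!r}")
        if node in self.taxa.values():
            raise ValueError(f"node {node} already carries a taxon label")
        self.taxa[label] = node

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> List[int]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> List[Edge]:
        return sorted(self._g.edges)

    def has_node(self, v: int) -> bool:
        return self._g.has_node(v)

    def has_edge(self, u: int, v: int) -> bool:
        return self._g.has_edge(u, v)

    def parents(self, v: int) -> List[int]:
        self._check_node(v)
        return sorted(self._g.predecessors(v))

    def children(self, v: int) -> List[int]:
        self._check_node(v)
        return sorted(self._g.successors(v))

    def in_degree(self, v: int) -> int:
        self._check_node(v)
        return self._g.in_degree(v)

    def out_degree(self, v: int) -> int:
        self._check_node(v)
        return self._g.out_degree(v)

    def in_edges(self, v: int) -> List[Edge]:
        return sorted(self._g.in_edges(v))

    def out_edges(self, v: int) -> List[Edge]:
        return sorted(self._g.out_edges(v))

    def is_leaf(self, v: int) -> bool:
        return self.out_degree(v) == 0

    def leaves(self) -> List[int]:
        return [v for v in self.nodes if self._g.out_degree(v) == 0]

    def taxon_of(self, v: int) -> Optional[str]:
        for label, node in self.taxa.items():
            if node == v:
                return label
        return None

    def reticulate_nodes(self) -> List[int]:
        return [v for v in self.nodes if self._g.in_degree(v) >= 2]

    def reticulate_edges(self, exclude_acceptors: bool = True) -> List[Edge]:
        """Edges into reticulate nodes; the displacement objective excludes
        transfer-acceptor edges, which is the default here."""
        out = []
        for e in self.edges:
            if self._g.in_degree(e[1]) >= 2:
                if exclude_acceptors and e in self.acceptor_flags:
                    continue
                out.append(e)
        return out

    def topological_order(self) -> List[int]:
        return list(nx.lexicographical_topological_sort(self._g))

    def graph(self) -> nx.DiGraph:
        """The underlying directed graph (shared, do not mutate)."""
        return self._g

    def copy(self) -> "PhyloNetwork":
        net = PhyloNetwork()
        net._g = self._g.copy()
        net._next_id = self._next_id
        net.root = self.root
        net.taxa = dict(self.taxa)
        net.weights = dict(self.weights)
        net.acceptor_flags = set(self.acceptor_flags)
        net.display_labels = dict(self.display_labels)
        return net

    def _check_node(self, v: int) -> None:
        if not self._g.has_node(v):
            raise KeyError(f"unknown node id {v}")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<PhyloNetwork |V|={self._g.number_of_nodes()} "
                f"|E|={self._g.number_of_edges()} taxa={len(self.taxa)}>")


def classify_node(net: PhyloNetwork, v: int) -> NodeKind:
    """Tree node iff in-degree <= 1, reticulate otherwise."""
    if net.in_degree(v) <= 1:
        return NodeKind.TREE
    return NodeKind.RETICULATE


def classify_edge(net: PhyloNetwork, e: Edge) -> EdgeKind:
    """Classify an edge by its target node and the acceptor designation.

    An edge into a tree node is a tree edge.  Among the incoming edges of
    a reticulate node carrying an acceptor flag, the flagged edge is the
    transfer-acceptor and its siblings are transfer edges; without a flag
    all incoming edges are plain reticulate edges.
    """
    u, v = e
    if not net.has_edge(u, v):
        raise KeyError(f"unknown edge {e}")
    if classify_node(net, v) is NodeKind.TREE:
        if e in net.acceptor_flags:
            raise ValueError(f"acceptor flag on edge {e} into a tree node")
        return EdgeKind.TREE
    flagged = [f for f in net.in_edges(v) if f in net.acceptor_flags]
    if not flagged:
        return EdgeKind.RETICULATE
    if e in net.acceptor_flags:
        return EdgeKind.TRANSFER_ACCEPTOR
    return EdgeKind.TRANSFER


def validate_network(net: PhyloNetwork) -> List[Violation]:
    """Check the six well-formedness rules; an empty list means valid.

    Violations are returned as data (rule name plus offending ids), never
    raised: an invalid network is a legitimate intermediate state during
    capture and interactive editing.
    """
    g = net.graph()
    out: List[Violation] = []

    if g.number_of_nodes() == 0:
        return [Violation("empty", message="network has no nodes")]

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        out.append(Violation("acyclicity", edges=tuple(cycle),
                             message="directed cycle present"))

    roots = [v for v in g.nodes if g.in_degree(v) == 0]
    if len(roots) != 1:
        out.append(Violation("single_root", nodes=tuple(sorted(roots)),
                             message=f"{len(roots)} nodes of in-degree 0"))
    if net.root is None or not g.has_node(net.root):
        out.append(Violation("root_declared", message="no declared root"))
    elif roots != [net.root] and sorted(roots) != [net.root]:
        if net.root not in roots:
            out.append(Violation("root_declared", nodes=(net.root,),
                                 message="declared root has in-degree > 0"))
    if net.root is not None and g.has_node(net.root):
        reachable = set(nx.descendants(g, net.root)) | {net.root}
        unreachable = set(g.nodes) - reachable
        if unreachable:
            out.append(Violation("connected", nodes=tuple(sorted(unreachable)),
                                 message="nodes unreachable from the root"))

    leaves = {v for v in g.nodes if g.out_degree(v) == 0}
    labeled = set(net.taxa.values())
    for v in sorted(labeled - leaves):
        out.append(Violation("taxa_bijection", nodes=(v,),
                             message="taxon label on a non-leaf node"))
    for v in sorted(leaves - labeled):
        out.append(Violation("taxa_bijection", nodes=(v,),
                             message="unlabeled leaf"))

    for v in sorted(g.nodes):
        if g.in_degree(v) == 1 and g.out_degree(v) == 1:
            out.append(Violation("through_node", nodes=(v,)))

    for v in sorted(leaves):
        if g.in_degree(v) > 1:
            out.append(Violation("leaf_in_degree", nodes=(v,),
                                 message=f"leaf with in-degree {g.in_degree(v)}"))

    for v in sorted(g.nodes):
        flagged = [e for e in net.in_edges(v) if e in net.acceptor_flags]
        if len(flagged) > 1:
            out.append(Violation("acceptor_unique", nodes=(v,),
                                 edges=tuple(flagged),
                                 message="multiple acceptor edges into one node"))
        if flagged and g.in_degree(v) < 2:
            out.append(Violation("acceptor_on_tree_node", nodes=(v,),
                                 edges=tuple(flagged),
                                 message="acceptor flag into a tree node"))
    return out


def labeled_isomorphic(a: PhyloNetwork, b: PhyloNetwork,
                       check_weights: bool = True,
                       weight_tol: float = 0.0) -> bool:
    """Labeled-DAG isomorphism preserving taxa, acceptor flags and weights.

    Internal display names are ignored; only the taxon labeling matters,
    which is the identity that round-trip serialization must preserve.
    """
    if len(a.taxa) != len(b.taxa) or set(a.taxa) != set(b.taxa):
        return False
    ga = _attributed(a, check_weights)
    gb = _attributed(b, check_weights)

    def node_match(x, y):
        return x["taxon"] == y["taxon"]

    def edge_match(x, y):
        if x["acceptor"] != y["acceptor"]:
            return False
        if not check_weights:
            return True
        wa, wb = x["weight"], y["weight"]
        if (wa is None) != (wb is None):
            return False
        if wa is None:
            return True
        return abs(wa - wb) <= weight_tol

    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        ga, gb, node_match=node_match, edge_match=edge_match)
    return matcher.is_isomorphic()


def _attributed(net: PhyloNetwork, with_weights: bool) -> nx.DiGraph:
    g = nx.DiGraph()
    taxon_by_node = {v: k for k, v in net.taxa.items()}
    for v in net.nodes:
        g.add_node(v, taxon=taxon_by_node.get(v))
    for e in net.edges:
        g.add_edge(*e, acceptor=e in net.acceptor_flags,
                   weight=net.weights.get(e) if with_weights else None)
    return g


# -- small builders used across modules and tests ----------------------

def network_from_edges(edges: Iterable[Edge],
                       taxa: Optional[Dict[str, int]] = None,
                       weights: Optional[Dict[Edge, float]] = None,
                       acceptors: Iterable[Edge] = ()) -> PhyloNetwork:
    """Build a network from explicit integer-id edges (ids are preserved)."""
    net = PhyloNetwork()
    ids = sorted({u for u, _ in edges} | {v for _, v in edges})
    for i in ids:
        while net._next_id <= i:
            net.add_node()
    present = set(ids)
    for v in net.nodes:
        if v not in present:
            net._g.remove_node(v)
    acceptors = set(acceptors)
    weights = weights or {}
    for e in edges:
        net.add_edge(*e, weight=weights.get(e), acceptor=e in acceptors)
    roots = [v for v in net.nodes if net.in_degree(v) == 0]
    net.root = roots[0] if len(roots) == 1 else None
    for label, node in (taxa or {}).items():
        net.add_taxon(label, node)
    return net
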