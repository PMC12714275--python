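"""Backbone trees and lowest stable ancestors.

The layout algorithms never position the nodes of a network directly on
its DAG; they first derive a spanning *backbone tree* ``B``.  In the
combining view every reticulate node is detached from its parents and
re-attached below its lowest stable ancestor (LSA) — the last node that
lies on every root-to-node path, i.e. its immediate dominator.  In the
transfer view a reticulate node carrying a transfer-acceptor designation
keeps only that acceptor edge (no rerouting); undesignated reticulations
fall back to the combining rule.  ``B`` spans every node of the network,
may contain through nodes (they carry coordinates and are only suppressed
at serialization), and may have leaves that are internal in the network —
these are the *unlabeled leaves* that the equal-spacing pass interpolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Literal, Optional, Set

import networkx as nx

from .network import PhyloNetwork

View = Literal["combining", "transfer"]


@dataclass
class BackboneTree:
    """Rooted spanning tree with an explicit child order per node.

    ``children`` doubles as the child-order map ``O``: permuting one of
    its lists is exactly the move the displacement optimizer performs.
    """

    root: int
    children: Dict[int, List[int]]
    parent: Dict[int, Optional[int]]
    unlabeled_leaves: Set[int] = field(default_factory=set)
    view: View = "combining"

    def leaves(self) -> List[int]:
        return [v for v in self.postorder() if not self.children[v]]

    @property
    def H(self) -> int:
        """Circular-layout modulus: number of backbone leaves, plus 1."""
        return len(self.leaves()) + 1

    def postorder(self) -> Iterator[int]:
        stack = [(self.root, False)]
        while stack:
            v, expanded = stack.pop()
            if expanded:
                yield v
            else:
                stack.append((v, True))
                for w in reversed(self.children[v]):
                    stack.append((w, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            for w in reversed(self.children[v]):
                stack.append(w)

    def edges(self) -> List[tuple]:
        return [(self.parent[v], v) for v in self.children if self.parent[v] is not None]

    def copy(self) -> "BackboneTree":
        return BackboneTree(
            root=self.root,
            children={v: list(c) for v, c in self.children.items()},
            parent=dict(self.parent),
            unlabeled_leaves=set(self.unlabeled_leaves),
            view=self.view,
        )


def lowest_stable_ancestor(net: PhyloNetwork, v: int) -> int:
    """Last node on all root-to-``v`` paths (the immediate dominator).

    Defined for every node except the root; for a tree node with a single
    parent this is simply that parent.
    """
    if v == net.root:
        raise ValueError("the root has no lowest stable ancestor")
    doms = _dominators(net)
    if v not in doms:
        raise ValueError(f"node {v} is unreachable from the root")
    return doms[v]


def _dominators(net: PhyloNetwork) -> Dict[int, int]:
    idom = nx.immediate_dominators(net.graph(), net.root)
    return {v: u for v, u in idom.items() if v != net.root}


def build_backbone(net: PhyloNetwork, view: View = "combining") -> BackboneTree:
    """Derive the backbone tree for the requested view.

    Every backbone edge runs from a dominator to a dominated node (tree
    nodes keep their unique parent; rerouted reticulations hang below
    their LSA) or is an acceptor edge of the network, so the result is
    acyclic and spans all nodes.  A transfer-view request on a reticulate
    node without an acceptor flag falls back to combining-style rerouting
    rather than failing.

    The default child order sorts siblings by the smallest taxon label in
    their backbone subtree (ties by node id), a deterministic starting
    point for the optimizer.
    """
    if net.root is None:
        raise ValueError("network has no root")
    doms = _dominators(net)
    parent: Dict[int, Optional[int]] = {net.root: None}
    for v in net.nodes:
        if v == net.root:
            continue
        if v not in doms:
            raise ValueError(f"node {v} is unreachable from the root")
        indeg = net.in_degree(v)
        if indeg <= 1:
            parent[v] = net.parents(v)[0]
        else:
            acceptors = [e for e in net.in_edges(v) if e in net.acceptor_flags]
            if view == "transfer" and acceptors:
                parent[v] = acceptors[0][0]
            else:
                parent[v] = doms[v]

    children: Dict[int, List[int]] = {v: [] for v in net.nodes}
    for v, p in parent.items():
        if p is not None:
            children[p].append(v)

    labeled = set(net.taxa.values())
    unlabeled = {v for v, c in children.items() if not c and v not in labeled}
    b = BackboneTree(root=net.root, children=children, parent=parent,
                     unlabeled_leaves=unlabeled, view=view)
    _apply_default_order(b, net)
    return b


def _apply_default_order(b: BackboneTree, net: PhyloNetwork) -> None:
    taxon_by_node = {v: k for k, v in net.taxa.items()}
    min_label: Dict[int, str] = {}
    for v in b.postorder():
        candidates = [min_label[w] for w in b.children[v] if w in min_label]
        own = taxon_by_node.get(v)
        if own is not None:
            candidates.append(own)
        if candidates:
            min_label[v] = min(candidates)
    sentinel = "￿"
    for v in b.children:
        b.children[v].sort(key=lambda w: (min_label.get(w, sentinel), w))
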