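"""Extended Newick input and output.

The extended Newick format encodes a rooted phylogenetic network in a
Newick-like string in which a reticulate node appears several times under
a shared tag: ``((a,(b)#H1),(#H1,c));`` describes a network whose ``#H1``
node has two parents and leaf ``b`` below it.  Accepted tag dialects are
``#H<i>``, ``#LGT<i>``, ``#R<i>`` and bare ``#<i>``.  A ``##`` occurrence
marks that incoming edge as the transfer-acceptor edge of the reticulation.
``:length`` suffixes attach branch lengths to the corresponding parent
edge, ``[&...]`` comment blocks are skipped, and labels may be quoted with
single quotes (doubled quotes escape).  Underscores are kept literal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .network import Edge, PhyloNetwork, validate_network

__all__ = ["ParseError", "parse_extended_newick", "write_extended_newick",
           "read_enewick_file", "write_enewick_file"]


class ParseError(ValueError):
    """Malformed extended Newick; carries the text position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


_TAG_RE = re.compile(r"(?:H|LGT|R)?\d+")
_UNQUOTED_STOP = set("(),;:#[]'")
_NEEDS_QUOTE = re.compile(r"[\s(),;:#\[\]']")


@dataclass
class _Occurrence:
    pos: int
    children: List["_Occurrence"] = field(default_factory=list)
    label: Optional[str] = None
    tag: Optional[str] = None
    acceptor: bool = False
    length: Optional[float] = None


class _Tokenizer:
    def __init__(self, text: str):
        self.text = text
        self.i = 0

    def _skip(self) -> None:
        while self.i < len(self.text):
            c = self.text[self.i]
            if c.isspace():
                self.i += 1
            elif c == "[":
                end = self.text.find("]", self.i)
                if end < 0:
                    raise ParseError("unterminated [...] comment", self.i)
                self.i = end + 1
            else:
                return

    def peek(self) -> Optional[str]:
        self._skip()
        return self.text[self.i] if self.i < len(self.text) else None

    def take(self, expected: str) -> None:
        if self.peek() != expected:
            raise ParseError(f"expected {expected!r}", self.i)
        self.i += 1

    def label(self) -> Optional[str]:
        self._skip()
        if self.i >= len(self.text):
            return None
        if self.text[self.i] == "'":
            out, i = [], self.i + 1
            while True:
                if i >= len(self.text):
                    raise ParseError("unterminated quoted label", self.i)
                if self.text[i] == "'":
                    if i + 1 < len(self.text) and self.text[i + 1] == "'":
                        out.append("'")
                        i += 2
                        continue
                    break
                out.append(self.text[i])
                i += 1
            self.i = i + 1
            return "".join(out)
        start = self.i
        while (self.i < len(self.text)
               and not self.text[self.i].isspace()
               and self.text[self.i] not in _UNQUOTED_STOP):
            self.i += 1
        return self.text[start:self.i] if self.i > start else None

    def number(self) -> float:
        self._skip()
        m = re.match(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?",
                     self.text[self.i:])
        if not m:
            raise ParseError("expected a number", self.i)
        self.i += m.end()
        return float(m.group(0))


def _parse_subtree(tok: _Tokenizer) -> _Occurrence:
    occ = _Occurrence(pos=tok.i)
    if tok.peek() == "(":
        tok.take("(")
        occ.children.append(_parse_subtree(tok))
        while tok.peek() == ",":
            tok.take(",")
            occ.children.append(_parse_subtree(tok))
        tok.take(")")
    occ.label = tok.label()
    if tok.peek() == "#":
        tok.take("#")
        if tok.peek() == "#":
            tok.take("#")
            occ.acceptor = True
        tag_pos = tok.i
        tag = tok.label()
        if tag is None or not _TAG_RE.fullmatch(tag):
            raise ParseError("malformed reticulation tag", tag_pos)
        occ.tag = tag
    if tok.peek() == ":":
        tok.take(":")
        occ.length = tok.number()
    return occ


def parse_extended_newick(text: str) -> List[PhyloNetwork]:
    """Parse one network per ``;``-terminated statement.

    Occurrences of the same reticulation tag (there must be at least two)
    merge into a single reticulate node; the occurrence carrying a subtree
    (or, failing that, the first in text order) contributes the children.
    Through nodes produced by redundant parentheses are contracted.
    """
    tok = _Tokenizer(text)
    nets: List[PhyloNetwork] = []
    while tok.peek() is not None:
        start = tok.i
        root = _parse_subtree(tok)
        tok.take(";")
        nets.append(_occurrences_to_network(root, start))
    if not nets:
        raise ParseError("no ';'-terminated statement found", 0)
    return nets


def _occurrences_to_network(root: _Occurrence, pos: int) -> PhyloNetwork:
    net = PhyloNetwork()
    by_tag: Dict[str, List[_Occurrence]] = {}

    def collect(o: _Occurrence) -> None:
        if o.tag is not None:
            by_tag.setdefault(o.tag, []).append(o)
        for c in o.children:
            collect(c)

    collect(root)
    for tag, occs in by_tag.items():
        if len(occs) < 2:
            raise ParseError(f"reticulation tag #{tag} used only once",
                             occs[0].pos)
        if sum(o.acceptor for o in occs) > 1:
            raise ParseError(f"multiple ## occurrences of tag {tag}",
                             occs[-1].pos)
        with_children = [o for o in occs if o.children]
        if len(with_children) > 1:
            raise ParseError(f"tag #{tag} has children at several occurrences",
                             with_children[1].pos)

    node_of_tag: Dict[str, int] = {}

    def node_for(o: _Occurrence) -> int:
        if o.tag is not None:
            if o.tag not in node_of_tag:
                node_of_tag[o.tag] = net.add_node()
            return node_of_tag[o.tag]
        return net.add_node()

    labels: Dict[int, str] = {}

    def build(o: _Occurrence) -> int:
        v = node_for(o)
        if o.label:
            prev = labels.get(v)
            if prev is not None and prev != o.label:
                raise ParseError(
                    f"conflicting labels {prev!r}/{o.label!r} on one node",
                    o.pos)
            labels[v] = o.label
        for c in o.children:
            w = build(c)
            try:
                net.add_edge(v, w, weight=c.length, acceptor=c.acceptor)
            except ValueError as exc:
                raise ParseError(str(exc), c.pos) from None
        return v

    root_id = build(root)
    net.root = root_id
    if not nx.is_directed_acyclic_graph(net.graph()):
        raise ParseError("reticulation tags induce a directed cycle", pos)

    _contract_through_nodes(net, labels)

    for v in net.leaves():
        if v in labels:
            try:
                net.add_taxon(labels[v], v)
            except ValueError as exc:
                raise ParseError(str(exc), pos) from None
    for v, lab in labels.items():
        if v not in net.taxa.values():
            net.display_labels[v] = lab
    return net


def _contract_through_nodes(net: PhyloNetwork,
                            labels: Dict[int, str]) -> None:
    changed = True
    while changed:
        changed = False
        for v in net.nodes:
            if net.in_degree(v) == 1 and net.out_degree(v) == 1 and v not in labels:
                (u, _), (_, w) = net.in_edges(v)[0], net.out_edges(v)[0]
                if net.has_edge(u, w):
                    continue
                wu = net.weights.get((u, v))
                wv = net.weights.get((v, w))
                weight = None
                if wu is not None or wv is not None:
                    weight = (wu or 0.0) + (wv or 0.0)
                acc = (u, v) in net.acceptor_flags or (v, w) in net.acceptor_flags
                net.remove_node(v)
                net.add_edge(u, w, weight=weight, acceptor=acc)
                changed = True
                break


# -- writing -----------------------------------------------------------

def write_extended_newick(net: PhyloNetwork, include_weights: bool = True,
                          strict: bool = True) -> str:
    """Serialize to a single ``;``-terminated statement.

    Per reticulate node, the first parent edge encountered in a preorder
    traversal (children visited in node-id order) carries the inline
    occurrence with the subtree; the other parents emit ``#tag`` stubs.
    The acceptor edge, if any, is written with ``##`` at its occurrence.
    With ``strict`` (default) a network failing validation is rejected.
    """
    if strict:
        violations = validate_network(net)
        if violations:
            raise ValueError(f"refusing to write invalid network: {violations}")
    if net.root is None:
        raise ValueError("network has no root")

    tags: Dict[int, str] = {}
    inline_parent: Dict[int, int] = {}
    for i, v in enumerate(sorted(net.reticulate_nodes()), start=1):
        tags[v] = f"H{i}"
    seen: set = set()
    stack = [net.root]
    while stack:  # preorder, children in id order
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        for w in reversed(net.children(v)):
            if net.in_degree(w) >= 2 and w not in inline_parent:
                inline_parent[w] = v
            stack.append(w)

    taxon_by_node = {v: k for k, v in net.taxa.items()}

    def name_of(v: int) -> str:
        lab = taxon_by_node.get(v) or net.display_labels.get(v, "")
        if lab and _NEEDS_QUOTE.search(lab):
            return "'" + lab.replace("'", "''") + "'"
        return lab

    def suffix(v: int, via: Optional[Edge]) -> str:
        s = ""
        if v in tags:
            s += "##" if (via is not None and via in net.acceptor_flags) else "#"
            s += tags[v]
        if include_weights and via is not None and via in net.weights:
            s += ":" + _fmt(net.weights[via])
        return s

    def emit(v: int, via: Optional[Edge]) -> str:
        if v in tags and not (via is None or inline_parent.get(v) == via[0]):
            return suffix(v, via)  # stub occurrence
        kids = net.children(v)
        inner = ""
        if kids:
            inner = "(" + ",".join(emit(w, (v, w)) for w in kids) + ")"
        return inner + name_of(v) + suffix(v, via)

    return emit(net.root, None) + ";"


def _fmt(w: float) -> str:
    return repr(w) if w != int(w) else str(int(w)) + ".0"


def read_enewick_file(path: str) -> List[PhyloNetwork]:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_extended_newick(fh.read())


def write_enewick_file(path: str, nets, include_weights: bool = True,
                       strict: bool = True) -> None:
    if isinstance(nets, PhyloNetwork):
        nets = [nets]
    with open(path, "w", encoding="utf-8") as fh:
        for net in nets:
            fh.write(write_extended_newick(net, include_weights=include_weights,
                                           strict=strict))
            fh.write("\n")
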