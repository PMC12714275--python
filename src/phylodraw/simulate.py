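"""Random network generation and rendering (SVG and raster fixtures).

The generator grows a random rooted binary tree on n leaves by uniform
edge attachment and then inserts h reticulations, each by subdividing an
ordered pair of tree edges and adding a reticulate edge between the two
new nodes.  Ordering the pair by the topological rank of the edge sources
makes acyclicity automatic.  Two pairing policies are offered:

``nested`` (default)
    any ordered pair, so a reticulation may run down its own lineage —
    adequate for combining-view (hybridization) networks;
``cross``
    time-consistent lateral transfers: every node carries a time, and a
    reticulation may only connect two tree edges whose time intervals
    overlap, at a common time.  Required when every reticulation is to
    carry a transfer-acceptor flag: without time consistency the
    transfer-depth adjustment has no finite fixpoint (a transfer running
    down its own acceptor lineage, or two transfers straddling each
    other's lineages, raise each other forever).

No claim is made that this matches any particular published simulator's
distribution; it is a validity-guaranteed fixture generator.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Tuple

import networkx as nx
import numpy as np

from .layout import LayoutResult, compute_layout
from .network import Edge, EdgeKind, PhyloNetwork, classify_edge

Pairing = Literal["nested", "cross"]


@dataclass
class SimulationSpec:
    n: int
    h: Optional[int] = None   # defaults to round(0.2 * n)
    seed: int = 0
    replicates: int = 1
    pairing: Pairing = "nested"
    acceptors: bool = False   # flag every reticulation's in-tree edge
    weights: bool = False     # random dyadic branch lengths

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two taxa")
        if self.h is None:
            self.h = round(0.2 * self.n)
        if self.h < 0:
            raise ValueError("negative reticulation count")


def random_network(spec: SimulationSpec) -> PhyloNetwork:
    """Draw one random network; deterministic per seed."""
    rng = random.Random(spec.seed)
    net = PhyloNetwork()
    root = net.add_node()
    net.root = root
    first = net.add_node()
    second = net.add_node()
    net.add_edge(root, first)
    net.add_edge(root, second)
    times: Dict[int, float] = {root: 0.0, first: 1.0, second: 1.0}
    leaves = [first, second]
    for _ in range(spec.n - 2):
        edges = net.edges
        u, v = edges[rng.randrange(len(edges))]
        s = net.add_node()
        leaf = net.add_node()
        net.remove_edge(u, v)
        net.add_edge(u, s)
        net.add_edge(s, v)
        net.add_edge(s, leaf)
        times[s] = (times[u] + times[v]) / 2.0
        times[leaf] = max(times.values()) + 1.0
        leaves.append(leaf)
    for i, leaf in enumerate(leaves, start=1):
        net.add_taxon(f"t{i}", leaf)

    for _ in range(spec.h):
        if not _add_reticulation(net, rng, times, spec.pairing, spec.acceptors):
            raise RuntimeError(
                f"could not place reticulation {len(net.reticulate_nodes()) + 1} "
                f"after retries (n={spec.n}, h={spec.h}, pairing={spec.pairing})")

    if spec.weights:
        for e in net.edges:
            net.weights[e] = rng.randrange(1, 17) / 8.0
    return net


def _tree_edges_in_topo_order(net: PhyloNetwork) -> List[Edge]:
    rank = {v: i for i, v in enumerate(net.topological_order())}
    tree_edges = [e for e in net.edges if net.in_degree(e[1]) <= 1]
    tree_edges.sort(key=lambda e: (rank[e[0]], rank[e[1]]))
    return tree_edges


def _add_reticulation(net: PhyloNetwork, rng: random.Random,
                      times: Dict[int, float], pairing: Pairing,
                      acceptors: bool, max_tries: int = 200) -> bool:
    for _ in range(max_tries):
        edges = _tree_edges_in_topo_order(net)
        if len(edges) < 2:
            return False
        i = rng.randrange(len(edges) - 1)
        j = rng.randrange(i + 1, len(edges))
        e1, e2 = edges[i], edges[j]
        a, b = e1
        c, d = e2
        if pairing == "cross":
            # contemporaneous-lineage condition: the edges' time spans
            # must overlap; both insertion points get the common time
            lo = max(times[a], times[c])
            hi = min(times[b], times[d])
            if not hi > lo:
                continue
            t1 = t2 = (lo + hi) / 2.0
        else:
            t1 = (times[a] + times[b]) / 2.0
            t2 = (times[c] + times[d]) / 2.0
        u1 = net.add_node()
        net.remove_edge(a, b)
        net.add_edge(a, u1)
        net.add_edge(u1, b)
        u2 = net.add_node()
        net.remove_edge(c, d)
        net.add_edge(c, u2)
        net.add_edge(u2, d)
        net.add_edge(u1, u2)
        times[u1], times[u2] = t1, t2
        if acceptors:
            net.acceptor_flags.add((c, u2))
        return True
    return False


# -- SVG rendering -----------------------------------------------------

def render_svg(net: PhyloNetwork, lr: LayoutResult,
               scale: float = 24.0, margin: float = 20.0,
               font_size: float = 10.0) -> str:
    """Serialize the drawing as SVG 1.1 text.

    Tree and transfer-acceptor edges become two-segment orthogonal paths,
    reticulate and transfer edges quadratic curves in a distinct style,
    and each taxon a text element (to the right of its leaf, or rotated
    radially in circular layouts).  Circular layouts replace the
    orthogonal polylines by a circular arc at the parent radius followed
    by a radial segment.
    """
    circ = lr.circular is not None
    if circ:
        pos = {v: _polar_to_cart(r * scale, a) for v, (r, a) in lr.circular.items()}
    else:
        pos = {v: (x * scale, y * scale) for v, (x, y) in lr.xy.items()}
    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    minx, miny = min(xs), min(ys)
    shift = (margin + 60.0 - minx if circ else margin - minx, margin - miny)
    pos = {v: (px + shift[0], py + shift[1]) for v, (px, py) in pos.items()}
    width = max(p[0] for p in pos.values()) + margin + 80
    height = max(p[1] for p in pos.values()) + margin + 20

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{height:.0f}">',
        '<g fill="none" stroke="black" stroke-width="1.5">',
    ]
    for e in net.edges:
        kind = classify_edge(net, e)
        v, w = e
        if kind in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR):
            if circ:
                parts.append(_arc_path(lr, v, w, scale, shift))
            else:
                (xv, yv), (xw, yw) = pos[v], pos[w]
                parts.append(f'<path d="M {xv:.2f} {yv:.2f} V {yw:.2f} '
                             f'H {xw:.2f}"/>')
        else:
            (xv, yv), (xw, yw) = pos[v], pos[w]
            mx, my = (xv + xw) / 2, (yv + yw) / 2
            cx, cy = mx + (yw - yv) * 0.15, my - (xw - xv) * 0.15
            parts.append(f'<path class="reticulate" stroke="#1f77b4" '
                         f'stroke-dasharray="4 2" d="M {xv:.2f} {yv:.2f} '
                         f'Q {cx:.2f} {cy:.2f} {xw:.2f} {yw:.2f}"/>')
    parts.append("</g>")
    parts.append(f'<g font-family="sans-serif" font-size="{font_size}" '
                 'fill="black">')
    for label, v in sorted(net.taxa.items()):
        px, py = pos[v]
        if circ:
            _, ang = lr.circular[v]
            flip = 90 < ang % 360 < 270
            rot = ang + 180 if flip else ang
            anchor = "end" if flip else "start"
            parts.append(f'<text x="{px:.2f}" y="{py:.2f}" text-anchor="{anchor}" '
                         f'transform="rotate({rot:.1f} {px:.2f} {py:.2f})" '
                         f'dx="4">{_esc(label)}</text>')
        else:
            parts.append(f'<text x="{px + 4:.2f}" y="{py + font_size / 3:.2f}">'
                         f'{_esc(label)}</text>')
    parts.append("</g>")
    parts.append("</svg>")
    return "\n".join(parts)


def _polar_to_cart(r: float, angle_deg: float) -> Tuple[float, float]:
    a = math.radians(angle_deg)
    return (r * math.cos(a), r * math.sin(a))


def _arc_path(lr: LayoutResult, v: int, w: int, scale: float, shift) -> str:
    rv, av = lr.circular[v]
    rw, aw = lr.circular[w]
    p1 = _polar_to_cart(rv * scale, av)
    p2 = _polar_to_cart(rv * scale, aw)
    p3 = _polar_to_cart(rw * scale, aw)
    pts = [(p[0] + shift[0], p[1] + shift[1]) for p in (p1, p2, p3)]
    da = (aw - av) % 360.0
    sweep = 1 if da <= 180 else 0
    large = 0
    r = rv * scale
    return (f'<path d="M {pts[0][0]:.2f} {pts[0][1]:.2f} '
            f'A {r:.2f} {r:.2f} 0 {large} {sweep} {pts[1][0]:.2f} {pts[1][1]:.2f} '
            f'L {pts[2][0]:.2f} {pts[2][1]:.2f}"/>')


def _esc(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


# -- raster fixtures for capture ---------------------------------------

@dataclass
class LabelBox:
    """Sidecar label record: text plus pixel bounding box (x0,y0,x1,y1)."""

    text: str
    x0: int
    y0: int
    x1: int
    y1: int

    def contains(self, px: int, py: int) -> bool:
        return self.x0 <= px <= self.x1 and self.y0 <= py <= self.y1


#: fixed per-character label metrics (no font engine involved)
CHAR_W, CHAR_H = 6, 10


def render_raster_fixture(net: PhyloNetwork, lr: LayoutResult,
                          scale: int = 14, margin: int = 10,
                          line_width: int = 1
                          ) -> Tuple[np.ndarray, List[LabelBox], Dict[int, Tuple[int, int]]]:
    """Black-on-white raster of the drawing plus a label-box sidecar.

    Only the line geometry is rasterized — label text lives exclusively in
    the sidecar, which is what lets capture tests bypass OCR.  Returns the
    image (uint8, 255 = background), the label boxes, and the pixel
    position of every node.  Deterministic for fixed inputs.
    """
    from skimage.draw import line as draw_line

    xs = [p[0] for p in lr.xy.values()]
    ys = [p[1] for p in lr.xy.values()]
    minx, miny = min(xs), min(ys)
    xscale = 2 * scale

    def to_px(v: int) -> Tuple[int, int]:
        x, y = lr.xy[v]
        return (margin + round((x - minx) * xscale),
                margin + round((y - miny) * scale))

    node_px = {v: to_px(v) for v in net.nodes}
    maxlab = max((len(t) for t in net.taxa), default=0)
    W = max(p[0] for p in node_px.values()) + margin + CHAR_W * maxlab + 12
    Hh = max(p[1] for p in node_px.values()) + margin + CHAR_H
    img = np.full((Hh, W), 255, dtype=np.uint8)

    def stroke(p: Tuple[int, int], q: Tuple[int, int]) -> None:
        rr, cc = draw_line(p[1], p[0], q[1], q[0])
        for off in range(line_width):
            r2 = np.clip(rr + off, 0, Hh - 1)
            img[r2, cc] = 0

    for e in net.edges:
        v, w = e
        pv, pw = node_px[v], node_px[w]
        if classify_edge(net, e) in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR):
            corner = (pv[0], pw[1])
            stroke(pv, corner)
            stroke(corner, pw)
        else:
            stroke(pv, pw)

    boxes = []
    for label, v in sorted(net.taxa.items()):
        px, py = node_px[v]
        boxes.append(LabelBox(label, px + 5, py - CHAR_H // 2,
                              px + 5 + CHAR_W * len(label), py + CHAR_H // 2))
    return img, boxes, node_px


def write_label_sidecar(path: str, boxes: List[LabelBox]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("text\tx0\ty0\tx1\ty1\n")
        for b in boxes:
            fh.write(f"{b.text}\t{b.x0}\t{b.y0}\t{b.x1}\t{b.y1}\n")


def read_label_sidecar(path: str) -> List[LabelBox]:
    boxes = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            text, x0, y0, x1, y1 = line.rstrip("\n").split("\t")
            boxes.append(LabelBox(text, int(x0), int(y0), int(x1), int(y1)))
    return boxes
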