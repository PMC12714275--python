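"""Topology capture from raster figures.

Published phylogenies are often available only as pictures.  This module
implements a capture workflow for figures drawn as dark, thin lines on a
white background: binarize, thin the drawing to a one-pixel skeleton,
detect node pixels (endpoints and branching points) with a neighbour-count
mask, flood-fill the skeleton into pixel paths between nodes, drop paths
hidden inside label boxes, then grow a rooted network outward from a
user-supplied root location, orienting each path away from the already
connected side and refusing any path whose insertion would create a
directed cycle.  Label boxes come from a pluggable provider — an OCR
engine in interactive use, or a sidecar fixture here — and are attached to
nearby leaves.

Post-processing operations mirror the manual clean-up a captured topology
usually needs: contracting through nodes, replacing an in-2/out-2 node by
two crossing edges (paired by stroke direction), and merging node sets.
All operations are deterministic for a fixed image and root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from .network import PhyloNetwork, Violation, validate_network
from .simulate import LabelBox

Pixel = Tuple[int, int]  # (row, col)
Orientation = Literal["left_right", "right_left", "top_bottom", "bottom_top", "radial"]

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class PixelPath:
    """Ordered 8-connected pixel chain between two node clusters.

    ``ends`` holds cluster ids; ``None`` marks a free end (a closed loop
    that touches no node at all, before root splitting).
    """

    pixels: List[Pixel]
    ends: Tuple[Optional[int], Optional[int]]


@dataclass
class SkeletonGraph:
    skeleton: np.ndarray
    clusters: Dict[int, List[Pixel]]            # cluster id -> pixels
    endpoints: Set[int]                         # ids of endpoint clusters
    junctions: Set[int]                         # ids of junction clusters
    paths: List[PixelPath]
    label_boxes: List[LabelBox] = field(default_factory=list)

    def centroid(self, cid: int) -> Tuple[float, float]:
        pts = self.clusters[cid]
        return (sum(p[0] for p in pts) / len(pts),
                sum(p[1] for p in pts) / len(pts))


@dataclass
class CaptureResult:
    network: PhyloNetwork
    node_positions: Dict[int, Tuple[float, float]]   # node -> (col, row) px
    unresolved_paths: List[PixelPath]
    orientation: Orientation
    violations: List[Violation] = field(default_factory=list)


# -- pixel-level steps -------------------------------------------------

def binarize(image: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
    """Foreground mask of dark-on-white artwork.

    ``threshold`` is a luminance fraction in [0, 1]; pixels strictly
    darker are foreground.  Without one, Otsu's method picks it.  Color
    images are first reduced to mean luminance.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    img = img.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    if threshold is None:
        if float(img.min()) == float(img.max()):
            raise ValueError("no drawable content (blank image)")
        threshold = float(threshold_otsu(img))
    mask = img < threshold
    if not mask.any():
        raise ValueError("no drawable content (empty foreground)")
    return mask


def skeletonize(grid: np.ndarray) -> np.ndarray:
    """Morphological thinning to unit-width lines (topology preserving)."""
    return _sk_skeletonize(np.asarray(grid, dtype=bool))


def _neighbor_counts(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(sk.astype(int), kernel, mode="constant")


#: 8-neighbourhood in circular order (N, NE, E, SE, S, SW, W, NW)
_CIRC = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _arc_counts(sk: np.ndarray) -> np.ndarray:
    """Number of 0->1 transitions around each pixel's 8-neighbourhood."""
    s = np.pad(sk.astype(np.uint8), 1)
    rings = np.stack([s[1 + dr:s.shape[0] - 1 + dr, 1 + dc:s.shape[1] - 1 + dc]
                      for dr, dc in _CIRC])
    nxt = np.roll(rings, -1, axis=0)
    return ((rings == 0) & (nxt == 1)).sum(axis=0)


def detect_nodes(sk: np.ndarray) -> SkeletonGraph:
    """Find endpoint and junction pixels with a neighbourhood mask.

    One skeleton neighbour marks an endpoint.  Junctions are pixels whose
    8-neighbourhood splits into three or more connected arcs (the
    Rutovitz crossing number): this distinguishes true branch points from
    corner pixels of a bent line, which have adjacent neighbours forming
    a single arc.  8-adjacent junction pixels merge into one node
    cluster.
    """
    counts = _neighbor_counts(sk)
    arcs = _arc_counts(sk)
    junction_mask = sk & (arcs >= 3)
    endpoint_mask = sk & (counts == 1)
    clusters: Dict[int, List[Pixel]] = {}
    junctions: Set[int] = set()
    endpoints: Set[int] = set()
    lab, nlab = ndimage.label(junction_mask, structure=np.ones((3, 3)))
    next_id = 0
    for i in range(1, nlab + 1):
        pts = [tuple(p) for p in np.argwhere(lab == i)]
        clusters[next_id] = sorted(pts)
        junctions.add(next_id)
        next_id += 1
    for p in sorted(map(tuple, np.argwhere(endpoint_mask))):
        clusters[next_id] = [p]
        endpoints.add(next_id)
        next_id += 1
    return SkeletonGraph(skeleton=sk, clusters=clusters, endpoints=endpoints,
                         junctions=junctions, paths=[])


def trace_paths(sg: SkeletonGraph) -> SkeletonGraph:
    """Partition non-node skeleton pixels into paths between clusters.

    Walks outward from every cluster along degree-1/2 chains; leftover
    pixels form closed loops, stored as paths with ``None`` ends.  Every
    skeleton pixel ends up in exactly one path or one cluster.
    """
    sk = sg.skeleton
    node_pixel: Dict[Pixel, int] = {}
    for cid, pts in sg.clusters.items():
        for p in pts:
            node_pixel[p] = cid
    skset = {tuple(p) for p in np.argwhere(sk)}
    assigned: Set[Pixel] = set()
    paths: List[PixelPath] = []

    def neighbors(p: Pixel) -> List[Pixel]:
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGH
                if (p[0] + dr, p[1] + dc) in skset]

    for cid in sorted(sg.clusters):
        for cp in sg.clusters[cid]:
            for start in sorted(neighbors(cp)):
                if start in node_pixel or start in assigned:
                    continue
                chain = [start]
                assigned.add(start)
                cur = start
                end_cluster: Optional[int] = None
                while True:
                    node_nbrs = [q for q in sorted(neighbors(cur))
                                 if q in node_pixel]
                    # node adjacency terminates the walk -- except that the
                    # first pixel must not end back in its origin cluster
                    terminal = node_nbrs if cur != start else \
                        [q for q in node_nbrs if node_pixel[q] != cid]
                    if terminal:
                        end_cluster = node_pixel[terminal[0]]
                        break
                    free = [q for q in sorted(neighbors(cur))
                            if q not in node_pixel and q not in assigned]
                    if free:
                        nxt = free[0]
                        chain.append(nxt)
                        assigned.add(nxt)
                        cur = nxt
                        continue
                    if node_nbrs:  # dead end at the origin: loop or stub
                        end_cluster = node_pixel[node_nbrs[0]]
                    break
                paths.append(PixelPath(pixels=chain, ends=(cid, end_cluster)))

    # single-pixel bridges: node pixels directly adjacent across clusters
    # are implicitly connected; loops with no node pixel remain:
    leftover = sorted(skset - assigned - set(node_pixel))
    while leftover:
        start = leftover[0]
        chain = [start]
        assigned.add(start)
        prev, cur = None, start
        while True:
            options = [q for q in sorted(neighbors(cur))
                       if q not in node_pixel and q not in assigned]
            if not options:
                break
            nxt = options[0]
            chain.append(nxt)
            assigned.add(nxt)
            prev, cur = cur, nxt
        paths.append(PixelPath(pixels=chain, ends=(None, None)))
        leftover = sorted(skset - assigned - set(node_pixel))

    sg.paths = _merge_dangling(paths, sg)
    return sg


def _merge_dangling(paths: List[PixelPath], sg: SkeletonGraph) -> List[PixelPath]:
    """Give dangling chain ends their own endpoint clusters."""
    next_id = max(sg.clusters, default=-1) + 1
    out = []
    for p in paths:
        a, bnd = p.ends
        if bnd is None and a is not None:
            if len(p.pixels) == 1:
                continue  # 1-pixel stray bump: dropped
            tip = p.pixels[-1]
            sg.clusters[next_id] = [tip]
            sg.endpoints.add(next_id)
            out.append(PixelPath(pixels=p.pixels[:-1], ends=(a, next_id)))
            next_id += 1
            continue
        out.append(p)
    return out


def filter_label_paths(paths: Sequence[PixelPath],
                       boxes: Sequence[LabelBox]) -> List[PixelPath]:
    """Drop paths lying entirely inside some label bounding box."""
    if not boxes:
        return list(paths)

    def inside(px: Pixel) -> bool:
        r, c = px
        return any(b.contains(c, r) for b in boxes)

    return [p for p in paths if not all(inside(px) for px in p.pixels)]


# -- assembly ----------------------------------------------------------

def assemble_network(sg: SkeletonGraph, root_location: Tuple[float, float],
                     label_boxes: Optional[Sequence[LabelBox]] = None,
                     root_tolerance: float = 5.0,
                     min_artifact: int = 4) -> CaptureResult:
    """Grow a rooted network from the traced paths.

    The skeleton pixel nearest to ``root_location`` (given as (col, row))
    becomes the root, splitting a path if it falls in a path interior.
    The drawing orientation is inferred from the root's position relative
    to the cloud of detected nodes and supplies the default direction of
    every inserted edge (away from the root along the drawing axis); a
    path both of whose insertions would close a directed cycle — or that
    never connects to the growing component — is left unresolved.  Labels
    are attached to the nearest node on the far side from the root; label
    texts landing on out-degree-0 nodes become taxa.
    """
    boxes = list(label_boxes if label_boxes is not None else sg.label_boxes)
    paths = filter_label_paths(sg.paths, boxes)
    # prune skeletonization artifacts: sub-threshold self-loop bumps and
    # spurs at stroke corners (standard skeleton pruning)
    paths = [p for p in paths
             if not (p.ends[0] == p.ends[1] and p.ends[0] is not None
                     and len(p.pixels) < min_artifact)]
    clusters = {cid: list(pts) for cid, pts in sg.clusters.items()}

    root_cid, paths = _place_root(sg, clusters, paths, root_location, root_tolerance)
    orientation = _infer_orientation(sg, clusters, root_cid)

    centroid = {cid: _centroid(pts) for cid, pts in clusters.items()}
    root_pos = centroid[root_cid]

    def axis_key(cid: int) -> float:
        r, c = centroid[cid]
        if orientation == "left_right":
            return c
        if orientation == "right_left":
            return -c
        if orientation == "top_bottom":
            return r
        if orientation == "bottom_top":
            return -r
        return math.hypot(r - root_pos[0], c - root_pos[1])

    g = nx.DiGraph()
    g.add_node(root_cid)
    added_at = {root_cid: 0}
    accepted: List[Tuple[int, int, PixelPath]] = []
    unresolved: List[PixelPath] = []
    pending = list(paths)
    counter = 1
    while True:
        candidates = [p for p in pending
                      if p.ends[0] in added_at or p.ends[1] in added_at]
        if not candidates:
            break
        candidates.sort(key=lambda p: (
            min(added_at.get(p.ends[0], math.inf),
                added_at.get(p.ends[1], math.inf)),
            len(p.pixels), p.pixels[0]))
        p = candidates[0]
        pending.remove(p)
        a, bnd = p.ends
        if a == bnd:
            unresolved.append(p)  # self-loop: always a directed cycle
            continue
        in_a, in_b = a in added_at, bnd in added_at
        if in_a and not in_b:
            src, dst = a, bnd
        elif in_b and not in_a:
            src, dst = bnd, a
        else:
            # both connected: direction along the drawing axis, ties by
            # insertion order (earlier-connected end is the source)
            ka, kb = axis_key(a), axis_key(bnd)
            if ka < kb:
                src, dst = a, bnd
            elif kb < ka:
                src, dst = bnd, a
            else:
                src, dst = (a, bnd) if added_at[a] <= added_at[bnd] else (bnd, a)
        if g.has_node(dst) and g.has_node(src) and nx.has_path(g, dst, src):
            if not nx.has_path(g, src, dst):
                src, dst = dst, src  # reversed insertion stays acyclic
            else:
                unresolved.append(p)
                continue
        if g.has_edge(src, dst):
            unresolved.append(p)  # parallel stroke
            continue
        g.add_edge(src, dst)
        accepted.append((src, dst, p))
        for cid in (src, dst):
            if cid not in added_at:
                added_at[cid] = counter
                counter += 1
    unresolved.extend(pending)  # never reached the component

    net = PhyloNetwork()
    node_of: Dict[int, int] = {}
    for cid in sorted(g.nodes):
        node_of[cid] = net.add_node()
    for src, dst, _ in accepted:
        net.add_edge(node_of[src], node_of[dst])
    net.root = node_of[root_cid]

    positions = {node_of[cid]: (centroid[cid][1], centroid[cid][0])
                 for cid in g.nodes}
    _attach_labels(net, node_of, centroid, boxes, root_pos, g)
    violations = validate_network(net)
    return CaptureResult(network=net, node_positions=positions,
                         unresolved_paths=unresolved, orientation=orientation,
                         violations=violations)


def _centroid(pts: Sequence[Pixel]) -> Tuple[float, float]:
    return (sum(p[0] for p in pts) / len(pts),
            sum(p[1] for p in pts) / len(pts))


def _place_root(sg, clusters, paths, root_location, tol):
    """Pick or create the root cluster nearest (col, row) root_location."""
    col, row = root_location
    best: Tuple[float, str, int, int] = (math.inf, "", -1, -1)
    for cid, pts in clusters.items():
        for p in pts:
            d = math.hypot(p[0] - row, p[1] - col)
            if d < best[0]:
                best = (d, "cluster", cid, 0)
    for i, path in enumerate(paths):
        for j, p in enumerate(path.pixels):
            d = math.hypot(p[0] - row, p[1] - col)
            if d < best[0]:
                best = (d, "path", i, j)
    if best[0] > tol:
        raise ValueError(f"root location {root_location} is {best[0]:.1f}px "
                         f"from the nearest drawing pixel (tolerance {tol})")
    if best[1] == "cluster":
        return best[2], paths
    # split the path at the chosen pixel
    i, j = best[2], best[3]
    path = paths[i]
    a, bnd = path.ends
    if a is None and bnd is None:  # closed loop: becomes one root->root path
        new_cid = max(clusters, default=-1) + 1
        clusters[new_cid] = [path.pixels[j]]
        rest = [p for k, p in enumerate(paths) if k != i]
        loop = PixelPath(pixels=path.pixels[j + 1:] + path.pixels[:j],
                         ends=(new_cid, new_cid))
        return new_cid, rest + [loop]
    if j == 0 and a is not None:
        return a, paths  # split point touches an existing end cluster
    if j == len(path.pixels) - 1 and bnd is not None:
        return bnd, paths
    new_cid = max(clusters, default=-1) + 1
    clusters[new_cid] = [path.pixels[j]]
    rest = [p for k, p in enumerate(paths) if k != i]
    left = PixelPath(pixels=path.pixels[:j], ends=(a, new_cid))
    right = PixelPath(pixels=path.pixels[j + 1:], ends=(new_cid, bnd))
    return new_cid, rest + [left, right]


def _infer_orientation(sg, clusters, root_cid) -> Orientation:
    pts = [p for cid, ps in clusters.items() for p in ps]
    if not pts:
        return "left_right"
    rows = [p[0] for p in pts]
    cols = [p[1] for p in pts]
    r0, r1, c0, c1 = min(rows), max(rows), min(cols), max(cols)
    rr, rc = _centroid(clusters[root_cid])
    # root within the central 25% (per axis) of the node bounding box -> radial
    def central(v, lo, hi):
        mid, half = (lo + hi) / 2, (hi - lo) * 0.125
        return abs(v - mid) <= max(half, 1.0)
    if central(rr, r0, r1) and central(rc, c0, c1) and (r1 - r0) > 4 and (c1 - c0) > 4:
        return "radial"
    dr = (r0 + r1) / 2 - rr
    dc = (c0 + c1) / 2 - rc
    if abs(dc) >= abs(dr):
        return "left_right" if dc >= 0 else "right_left"
    return "top_bottom" if dr >= 0 else "bottom_top"


def _attach_labels(net, node_of, centroid, boxes, root_pos, g) -> None:
    for box in sorted(boxes, key=lambda b: (b.y0, b.x0, b.text)):
        bc = ((box.y0 + box.y1) / 2, (box.x0 + box.x1) / 2)  # (row, col)
        best_cid, best_d = None, math.inf
        for cid in g.nodes:
            d = math.hypot(centroid[cid][0] - bc[0], centroid[cid][1] - bc[1])
            if d < best_d:
                best_cid, best_d = cid, d
        if best_cid is None:
            continue
        node = node_of[best_cid]
        if net.out_degree(node) == 0 and node not in net.taxa.values() \
                and box.text and box.text not in net.taxa:
            net.add_taxon(box.text, node)
        elif box.text:
            net.display_labels[node] = box.text


# -- capture pipeline convenience --------------------------------------

def capture_network(image: np.ndarray, root_location: Tuple[float, float],
                    label_boxes: Optional[Sequence[LabelBox]] = None,
                    threshold: Optional[float] = None,
                    root_tolerance: float = 5.0) -> CaptureResult:
    """Run the full pipeline: binarize, thin, detect, trace, assemble."""
    mask = binarize(image, threshold=threshold)
    sk = skeletonize(mask)
    sg = detect_nodes(sk)
    trace_paths(sg)
    if label_boxes:
        sg.label_boxes = list(label_boxes)
    return assemble_network(sg, root_location, label_boxes=label_boxes,
                            root_tolerance=root_tolerance)


# -- topology post-processing ------------------------------------------

def remove_through_nodes(net: PhyloNetwork,
                         positions: Optional[Dict[int, Tuple[float, float]]] = None
                         ) -> PhyloNetwork:
    """Contract every in-1/out-1 node; incident weights sum when present.

    A through node whose contraction would create a parallel edge is left
    in place.  ``positions`` (if given) is pruned in step.
    """
    net = net.copy()
    changed = True
    while changed:
        changed = False
        for v in net.nodes:
            if net.in_degree(v) == 1 and net.out_degree(v) == 1:
                (u, _) = net.in_edges(v)[0]
                (_, w) = net.out_edges(v)[0]
                if u == w or net.has_edge(u, w):
                    continue
                w_in = net.weights.get((u, v))
                w_out = net.weights.get((v, w))
                weight = None
                if w_in is not None or w_out is not None:
                    weight = (w_in or 0.0) + (w_out or 0.0)
                acc = (u, v) in net.acceptor_flags or (v, w) in net.acceptor_flags
                net.remove_node(v)
                if positions is not None:
                    positions.pop(v, None)
                net.add_edge(u, w, weight=weight, acceptor=acc)
                changed = True
                break
    return net


def replace_with_crossing(net: PhyloNetwork, v: int,
                          positions: Dict[int, Tuple[float, float]]
                          ) -> PhyloNetwork:
    """Replace an in-2/out-2 node by two independent crossing edges.

    Each incoming stroke is paired with the outgoing stroke it is most
    nearly collinear with (judged from the node positions); the symmetric
    tie breaks deterministically toward the smaller-id out-neighbour.
    """
    if net.in_degree(v) != 2 or net.out_degree(v) != 2:
        raise ValueError(f"node {v} is not in-2/out-2 "
                         f"(in={net.in_degree(v)}, out={net.out_degree(v)})")
    net = net.copy()
    (a1, _), (a2, _) = net.in_edges(v)
    (_, b1), (_, b2) = net.out_edges(v)

    def direction(p: int, q: int) -> Tuple[float, float]:
        (x1, y1), (x2, y2) = positions[p], positions[q]
        dx, dy = x2 - x1, y2 - y1
        norm = math.hypot(dx, dy) or 1.0
        return dx / norm, dy / norm

    def alignment(a: int, b: int) -> float:
        da = direction(a, v)
        db = direction(v, b)
        return da[0] * db[0] + da[1] * db[1]  # cosine of the turn

    straight = alignment(a1, b1) + alignment(a2, b2)
    crossed = alignment(a1, b2) + alignment(a2, b1)
    if crossed > straight + 1e-12:
        pairs = [(a1, b2), (a2, b1)]
    else:
        pairs = [(a1, b1), (a2, b2)]
    wsum: Dict[int, Optional[float]] = {}
    for a, b in pairs:
        w_in = net.weights.get((a, v))
        w_out = net.weights.get((v, b))
        wsum[b] = None if (w_in is None and w_out is None) \
            else (w_in or 0.0) + (w_out or 0.0)
    net.remove_node(v)
    for a, b in pairs:
        if not net.has_edge(a, b):
            net.add_edge(a, b, weight=wsum[b])
    return net


def merge_nodes(net: PhyloNetwork, nodes: Set[int]) -> PhyloNetwork:
    """Merge a node set into one node, keeping labels and connectivity.

    External edges are deduplicated, internal edges become discarded
    self-loops, and the merged node inherits the union of labels — two
    distinct taxon labels in one merge are an error (the taxon map must
    stay a bijection).  Merging the root into the set makes the merged
    node the root; a merge that would leave the root orphaned (its only
    path to the rest removed) is rejected by validation downstream.
    """
    nodes = set(nodes)
    if not nodes:
        raise ValueError("empty merge set")
    for v in nodes:
        net._check_node(v)
    if len(nodes) == 1:
        return net.copy()
    taxa_in = [lab for lab, n in net.taxa.items() if n in nodes]
    if len(taxa_in) > 1:
        raise ValueError(f"merging would collapse taxa {taxa_in}")
    net2 = net.copy()
    keep = min(nodes)
    others = nodes - {keep}
    for v in others:
        for (u, _) in net2.in_edges(v):
            if u not in nodes and not net2.has_edge(u, keep):
                net2.add_edge(u, keep, weight=net2.weights.get((u, v)),
                              acceptor=(u, v) in net2.acceptor_flags)
        for (_, w) in net2.out_edges(v):
            if w not in nodes and not net2.has_edge(keep, w):
                net2.add_edge(keep, w, weight=net2.weights.get((v, w)),
                              acceptor=(v, w) in net2.acceptor_flags)
    label = None
    for v in sorted(nodes):
        if v in net2.display_labels:
            label = label or net2.display_labels[v]
    for v in others:
        net2.remove_node(v)
    if taxa_in and net2.taxa.get(taxa_in[0]) is None:
        net2.taxa[taxa_in[0]] = keep
    if label is not None:
        net2.display_labels[keep] = label
    if net.root in others:
        net2.root = keep
    # drop edges internal to the merge set that became self-loops: they
    # were removed with their endpoints; nothing else to do
    return net2
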