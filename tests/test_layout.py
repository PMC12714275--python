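import itertools

import pytest
from hypothesis import given, settings, strategies as st

import phylodraw as pd
from phylodraw.layout import (adjust_transfer_depths, apply_late_layout,
                              assign_x_phylogram, assign_y, compute_depths,
                              count_crossings, equalize_leaf_spacing,
                              to_circular, tree_edge_segments)
from phylodraw.network import EdgeKind, classify_edge, network_from_edges
from phylodraw.simulate import SimulationSpec, random_network


class TestAssignY:
    def test_two_leaf_means(self, two_leaf_tree):
        b = pd.build_backbone(two_leaf_tree)
        y = assign_y(b)
        ya, yb = y[two_leaf_tree.taxa["a"]], y[two_leaf_tree.taxa["b"]]
        assert sorted([ya, yb]) == [0.0, 1.0]
        assert y[two_leaf_tree.root] == 0.5

    def test_caterpillar_children_mean(self, caterpillar):
        b = pd.build_backbone(caterpillar)
        y = assign_y(b, "children_mean")
        assert y[caterpillar.root] == pytest.approx(1.25)

    def test_caterpillar_descendant_leaf_mean(self, caterpillar):
        b = pd.build_backbone(caterpillar)
        y = assign_y(b, "descendant_leaf_mean")
        assert y[caterpillar.root] == pytest.approx(1.0)

    def test_leaves_get_distinct_consecutive_integers(self):
        net = random_network(SimulationSpec(n=11, h=3, seed=2))
        b = pd.build_backbone(net)
        y = assign_y(b)
        leaf_ys = sorted(y[v] for v in b.leaves())
        assert leaf_ys == [float(i) for i in range(len(b.leaves()))]


class TestDepths:
    def test_leaf_below_root(self, two_leaf_tree):
        d = compute_depths(two_leaf_tree)
        assert d[two_leaf_tree.taxa["a"]] == 1

    def test_diamond_takes_max_path(self):
        net = network_from_edges(
            [(0, 1), (0, 2), (1, 2), (2, 3), (1, 4)],
            taxa={"a": 3, "b": 4})
        d = compute_depths(net)
        assert d[2] == 2

    def test_chain_depth(self):
        edges = [(i, i + 1) for i in range(5)] + [(0, 9)]
        net = network_from_edges(edges, taxa={"a": 5, "b": 9})
        assert compute_depths(net)[5] == 5


def brute_force_smallest_fixpoint(net, d0, bound=100):
    """Oracle: smallest d >= d0 with d(v) >= d(w) on transfer edges and
    d strictly increasing along tree/acceptor edges, by chaotic iteration
    one constraint at a time."""
    d = dict(d0)
    transfer = [e for e in net.edges
                if classify_edge(net, e) is EdgeKind.TRANSFER]
    mono = [e for e in net.edges
            if classify_edge(net, e) in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR)]
    for _ in range(bound):
        changed = False
        for v, w in transfer:
            if d[v] < d[w]:
                d[v] = d[w]
                changed = True
        for u, v in mono:
            if d[v] <= d[u]:
                d[v] = d[u] + 1
                changed = True
        if not changed:
            return d
    raise RuntimeError("no fixpoint")


class TestTransferDepths:
    def test_no_transfer_edges_identity(self, hybrid_net):
        d = compute_depths(hybrid_net)
        assert adjust_transfer_depths(hybrid_net, d) == d

    def test_single_transfer_edge_raises_source(self):
        # root -> a -> b(leaf), root -> c -> d -> w; transfer a -> w,
        # acceptor d -> w, w -> leaf.  d(a)=1 < d(w)=3.
        net = network_from_edges(
            [(0, 1), (1, 2), (0, 3), (3, 4), (4, 5), (1, 5), (5, 6), (1, 7)],
            taxa={"b": 2, "w": 6, "x": 7}, acceptors=[(4, 5)])
        d0 = compute_depths(net)
        assert d0[1] == 1 and d0[5] == 3
        d = adjust_transfer_depths(net, d0)
        assert d[1] == 3
        # a's tree descendants shifted to stay strictly deeper
        assert d[2] > d[1] and d[7] > d[1]
        assert d == brute_force_smallest_fixpoint(net, d0)

    def test_mutually_influencing_transfers_reach_fixpoint(self):
        for seed in range(20):
            net = random_network(SimulationSpec(
                n=7, h=3, seed=seed, pairing="cross", acceptors=True))
            d0 = compute_depths(net)
            d = adjust_transfer_depths(net, d0)
            assert d == brute_force_smallest_fixpoint(net, d0)
            for v, w in net.edges:
                if classify_edge(net, (v, w)) is EdgeKind.TRANSFER:
                    assert d[v] >= d[w]

    def test_time_inconsistent_transfer_raises(self):
        # transfer edge descending its own acceptor lineage: a -> w where
        # a is an ancestor of w's acceptor parent -> no finite fixpoint
        net = network_from_edges(
            [(0, 1), (1, 2), (2, 3), (1, 3), (3, 4), (2, 5), (0, 6)],
            taxa={"w": 4, "x": 5, "y": 6}, acceptors=[(2, 3)])
        with pytest.raises(RuntimeError):
            adjust_transfer_depths(net, compute_depths(net))


class TestPhylogram:
    def test_simple_weighted_path(self):
        net = pd.parse_extended_newick("(a:2.5,b:1.0);")[0]
        x = assign_x_phylogram(net)
        assert x[net.taxa["a"]] == 2.5

    def test_combining_node_max_plus_delta(self):
        net = network_from_edges(
            [(0, 1), (0, 2), (1, 3), (2, 3), (3, 4), (1, 5), (2, 6)],
            taxa={"a": 4, "b": 5, "c": 6},
            weights={(0, 1): 1.0, (0, 2): 3.0, (3, 4): 1.0,
                     (1, 5): 1.0, (2, 6): 1.0})
        x = assign_x_phylogram(net, delta=0.1)
        assert x[3] == pytest.approx(3.1)

    def test_zero_weights_degenerate(self):
        net = pd.parse_extended_newick("((a:0,(b:0)#H1:0):0,(#H1:0,c:0):0);")[0]
        x = assign_x_phylogram(net, delta=0.25)
        ret = net.reticulate_nodes()[0]
        for v in net.nodes:
            if net.in_degree(v) <= 1 and v != ret:
                assert x[v] == 0.0 or v in net.children(ret)
        assert x[ret] == 0.25

    def test_missing_weight_raises_and_names_edge(self):
        net = pd.parse_extended_newick("(a:1.0,b);")[0]
        with pytest.raises(ValueError, match="missing branch length"):
            assign_x_phylogram(net)

    def test_exact_weight_differences_and_left_to_right(self):
        for seed in range(10):
            net = random_network(SimulationSpec(n=10, h=3, seed=seed,
                                                weights=True))
            x = assign_x_phylogram(net, delta=1 / 64)
            for e in net.edges:
                k = classify_edge(net, e)
                v, w = e
                if k in (EdgeKind.TREE, EdgeKind.TRANSFER_ACCEPTOR):
                    assert x[w] - x[v] == net.weights[e]
                else:
                    assert x[w] > x[v]


class TestLateLayout:
    def test_balanced_tree_unchanged(self):
        net = pd.parse_extended_newick("((a,b),(c,d));")[0]
        x = {v: float(d) for v, d in compute_depths(net).items()}
        assert apply_late_layout(net, x) == x

    def test_caterpillar_pushes_leaves_right(self, caterpillar):
        x = {v: float(d) for v, d in compute_depths(caterpillar).items()}
        late = apply_late_layout(caterpillar, x)
        assert late[caterpillar.taxa["c"]] == 2.0  # right-aligned leaf
        inner = caterpillar.parents(caterpillar.taxa["a"])[0]
        assert late[inner] == 1.0
        assert late[caterpillar.root] == 0.0

    def test_chain_unchanged(self):
        net = pd.parse_extended_newick("((((a,b)))) ;".replace(" ", ""))[0]
        x = {v: float(d) for v, d in compute_depths(net).items()}
        assert apply_late_layout(net, x) == x

    def test_strictly_increasing_along_every_edge(self):
        net = random_network(SimulationSpec(n=12, h=3, seed=7))
        x = {v: float(d) for v, d in compute_depths(net).items()}
        late = apply_late_layout(net, x)
        for v, w in net.edges:
            assert late[v] < late[w]

    def test_late_phylogram_rejected(self, caterpillar):
        with pytest.raises(ValueError):
            pd.compute_layout(caterpillar, style="phylogram", timing="late")


class TestEqualSpacing:
    def test_no_unlabeled_leaves_identity(self, caterpillar):
        b = pd.build_backbone(caterpillar)
        assert equalize_leaf_spacing(b, caterpillar) == assign_y(b)

    def test_single_gap_midpoint(self):
        # backbone with leaf order labeled, unlabeled, labeled via a
        # reticulation that strands an internal node as a backbone leaf
        from phylodraw.backbone import BackboneTree
        net = network_from_edges([(0, 1), (0, 2), (0, 3)],
                                 taxa={"a": 1, "b": 3})
        b = pd.build_backbone(net)
        b.children[0] = [1, 2, 3]
        y = equalize_leaf_spacing(b, net)
        assert (y[1], y[2], y[3]) == (0.0, 0.5, 1.0)

    def test_double_gap_thirds(self):
        net = network_from_edges([(0, 1), (0, 2), (0, 3), (0, 4)],
                                 taxa={"a": 1, "b": 4})
        b = pd.build_backbone(net)
        b.children[0] = [1, 2, 3, 4]
        y = equalize_leaf_spacing(b, net)
        assert (y[1], y[2], y[3], y[4]) == \
            (0.0, pytest.approx(1 / 3), pytest.approx(2 / 3), 1.0)

    def test_preserves_relative_leaf_order(self):
        for seed in range(10):
            net = random_network(SimulationSpec(n=9, h=3, seed=seed))
            b = pd.optimize_child_orders(net, pd.build_backbone(net))
            y0 = assign_y(b)
            y1 = equalize_leaf_spacing(b, net)
            leaves = b.leaves()
            order0 = sorted(leaves, key=lambda v: y0[v])
            order1 = sorted(leaves, key=lambda v: y1[v])
            assert order0 == order1
            labeled = [v for v in order1 if v in net.taxa.values()]
            assert [y1[v] for v in labeled] == [float(i) for i in
                                                range(len(labeled))]


class TestCircular:
    def test_three_leaf_angles(self):
        net = pd.parse_extended_newick("(a,b,c);")[0]
        lr = pd.compute_layout(net, optimize=False, circular=True,
                               equal_spacing=False)
        assert lr.H == 4
        angles = sorted(lr.circular[v][1] for v in net.leaves())
        assert angles == [pytest.approx(0.0), pytest.approx(90.0),
                          pytest.approx(180.0)]

    def test_radius_is_x_plus_offset(self):
        net = pd.parse_extended_newick("((a,b),c);")[0]
        lr = pd.compute_layout(net, optimize=False, circular=True, r0=2.0)
        for v in net.nodes:
            assert lr.circular[v][0] == pytest.approx(lr.xy[v][0] + 2.0)

    @given(st.floats(0, 100), st.integers(2, 60))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_recovers_y(self, y, H):
        from phylodraw.layout import LayoutResult
        lr = LayoutResult(xy={0: (0.0, y % H)}, H=H)
        circ = to_circular(lr)
        angle = circ.circular[0][1]
        assert angle * H / 360.0 == pytest.approx(y % H, abs=1e-9)


class TestCrossings:
    @pytest.mark.parametrize("timing", ["early", "late"])
    @pytest.mark.parametrize("seed", range(8))
    def test_tree_edges_never_cross_in_combining_cladogram(self, seed, timing):
        net = random_network(SimulationSpec(n=12, h=3, seed=seed))
        lr = pd.compute_layout(net, timing=timing, seed=seed)
        assert count_crossings(tree_edge_segments(net, lr)) == 0

    def test_crossing_detector_detects_planted_crossing(self):
        segs = [((0, 1), ((0.0, 0.0), (0.0, 2.0))),
                ((2, 3), ((-1.0, 1.0), (1.0, 1.0)))]
        assert count_crossings(segs) == 1
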