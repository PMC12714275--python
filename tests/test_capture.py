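import numpy as np
import pytest
from skimage.draw import line as draw_line, polygon_perimeter

import phylodraw as pd
from phylodraw.capture import (assemble_network, binarize, capture_network,
                               detect_nodes, filter_label_paths, merge_nodes,
                               remove_through_nodes, replace_with_crossing,
                               skeletonize, trace_paths)
from phylodraw.network import network_from_edges
from phylodraw.simulate import (LabelBox, SimulationSpec, random_network,
                                render_raster_fixture)


def straight_line_image(length=30):
    img = np.zeros((11, length + 10), dtype=bool)
    img[5, 5:5 + length] = True
    return img


class TestBinarize:
    def test_all_white_raises(self):
        with pytest.raises(ValueError, match="no drawable content"):
            binarize(np.full((10, 10), 255, dtype=np.uint8))

    def test_black_line_is_foreground(self):
        img = np.full((9, 9), 255, dtype=np.uint8)
        img[4, 1:8] = 0
        mask = binarize(img)
        assert mask[4, 1:8].all()
        assert mask.sum() == 7

    def test_antialiased_gray_included_at_explicit_threshold(self):
        img = np.full((5, 5), 1.0)
        img[2, 1:4] = 0.0
        img[1, 1:4] = 0.5  # antialiased fringe
        mask = binarize(img, threshold=0.6)
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 1:4] = True
        expected[1, 1:4] = True
        assert np.array_equal(mask, expected)

    def test_color_image_reduced_by_luminance(self):
        img = np.full((6, 6, 3), 255, dtype=np.uint8)
        img[3, 1:5] = (10, 10, 10)
        assert binarize(img)[3, 1:5].all()


class TestSkeletonize:
    def test_thick_bar_thins_to_unit_width(self):
        img = np.zeros((9, 40), dtype=bool)
        img[3:6, 1:39] = True  # 3px-thick bar
        sk = skeletonize(img)
        assert sk.sum() >= 30
        # unit width: no pixel has a vertical 2-neighbour stack
        assert not (sk[:-1] & sk[1:]).any()

    def test_idempotent_on_thin_input(self):
        img = straight_line_image()
        sk = skeletonize(img)
        assert np.array_equal(skeletonize(sk), sk)

    def test_plus_blob_keeps_one_junction(self):
        img = np.zeros((31, 31), dtype=bool)
        img[14:17, 3:28] = True
        img[3:28, 14:17] = True
        sg = detect_nodes(skeletonize(img))
        assert len(sg.junctions) == 1
        assert len(sg.endpoints) == 4

    def test_homotopy_preserved_on_loop(self):
        from scipy import ndimage
        img = np.zeros((40, 40), dtype=bool)
        img[5:35, 5:35] = True
        img[10:30, 10:30] = False  # square annulus: one hole
        sk = skeletonize(img)
        ncomp = ndimage.label(sk, structure=np.ones((3, 3)))[1]
        nholes = ndimage.label(~sk)[1] - 1  # background minus outside
        assert ncomp == 1 and nholes == 1


class TestDetectNodes:
    def test_straight_line(self):
        sg = detect_nodes(straight_line_image())
        assert len(sg.endpoints) == 2 and len(sg.junctions) == 0

    def test_t_shape(self):
        img = np.zeros((30, 30), dtype=bool)
        img[5:25, 15] = True
        img[15, 15:28] = True
        sg = detect_nodes(img)
        assert len(sg.endpoints) == 3 and len(sg.junctions) == 1

    def test_x_shape_single_crossing_cluster(self):
        img = np.zeros((31, 31), dtype=bool)
        for i in range(31):
            img[i, i] = True
            img[i, 30 - i] = True
        sg = detect_nodes(img)
        assert len(sg.endpoints) == 4 and len(sg.junctions) == 1

    def test_corner_is_not_a_junction(self):
        img = np.zeros((20, 20), dtype=bool)
        img[3:15, 3] = True
        img[15, 3:15] = True
        sg = detect_nodes(img)
        assert len(sg.junctions) == 0 and len(sg.endpoints) == 2


class TestTracePaths:
    def test_straight_line_one_path(self):
        sg = detect_nodes(straight_line_image())
        trace_paths(sg)
        assert len(sg.paths) == 1
        ends = set(sg.paths[0].ends)
        assert ends == sg.endpoints

    def test_t_shape_three_paths(self):
        img = np.zeros((30, 30), dtype=bool)
        img[5:25, 15] = True
        img[15, 15:28] = True
        sg = detect_nodes(img)
        trace_paths(sg)
        assert len(sg.paths) == 3
        junction = next(iter(sg.junctions))
        assert all(junction in p.ends for p in sg.paths)

    def test_two_disjoint_lines(self):
        img = np.zeros((20, 40), dtype=bool)
        img[5, 5:35] = True
        img[15, 5:35] = True
        sg = detect_nodes(img)
        trace_paths(sg)
        assert len(sg.paths) == 2 and len(sg.endpoints) == 4

    def test_pixel_partition(self):
        """Every skeleton pixel is in exactly one path or one cluster."""
        net = random_network(SimulationSpec(n=8, h=0, seed=3))
        lr = pd.compute_layout(net, optimize=False, equal_spacing=False)
        img, _, _ = render_raster_fixture(net, lr)
        sk = skeletonize(binarize(img))
        sg = detect_nodes(sk)
        trace_paths(sg)
        cluster_px = [p for pts in sg.clusters.values() for p in pts]
        path_px = [p for path in sg.paths for p in path.pixels]
        allpx = cluster_px + path_px
        assert len(allpx) == len(set(allpx)) == int(sk.sum())


class TestFilterLabelPaths:
    def box(self):
        return LabelBox("t", 10, 10, 20, 20)

    def make_path(self, pixels):
        from phylodraw.capture import PixelPath
        return PixelPath(pixels=pixels, ends=(0, 1))

    def test_fully_inside_removed(self):
        p = self.make_path([(12, 12), (12, 13)])
        assert filter_label_paths([p], [self.box()]) == []

    def test_crossing_boundary_kept(self):
        p = self.make_path([(12, 12), (12, 25)])
        assert filter_label_paths([p], [self.box()]) == [p]

    def test_no_boxes_identity(self):
        p = self.make_path([(12, 12)])
        assert filter_label_paths([p], []) == [p]


class TestAssembleNetwork:
    def test_three_leaf_tree_round_trip(self):
        net = pd.parse_extended_newick("((a,b),c);")[0]
        lr = pd.compute_layout(net, optimize=False, equal_spacing=False)
        img, boxes, node_px = render_raster_fixture(net, lr)
        res = capture_network(img, node_px[net.root], label_boxes=boxes)
        cap = remove_through_nodes(res.network)
        assert pd.labeled_isomorphic(net, cap, check_weights=False)
        assert res.unresolved_paths == []
        assert res.orientation == "left_right"

    def test_reticulate_network_round_trip(self, hybrid_net):
        lr = pd.compute_layout(hybrid_net, seed=0, equal_spacing=False)
        img, boxes, node_px = render_raster_fixture(hybrid_net, lr)
        res = capture_network(img, node_px[hybrid_net.root], label_boxes=boxes)
        cap = remove_through_nodes(res.network)
        assert pd.labeled_isomorphic(hybrid_net, cap, check_weights=False)

    def test_triangle_cycle_leaves_one_unresolved(self):
        img = np.full((120, 140), 255, dtype=np.uint8)
        rr, cc = polygon_perimeter([10, 100, 100], [70, 20, 120],
                                   shape=img.shape)
        img[rr, cc] = 0
        res = capture_network(img, (70, 10))  # root on the top corner
        assert len(res.unresolved_paths) == 1

    def test_root_far_from_drawing_raises(self):
        net = pd.parse_extended_newick("(a,b);")[0]
        lr = pd.compute_layout(net, optimize=False)
        img, boxes, _ = render_raster_fixture(net, lr)
        with pytest.raises(ValueError, match="root location"):
            capture_network(img, (0, 0), label_boxes=boxes, root_tolerance=3)

    def test_valid_after_through_node_removal(self):
        for seed in range(5):
            net = random_network(SimulationSpec(n=6 + seed, h=0, seed=seed))
            lr = pd.compute_layout(net, optimize=False, equal_spacing=False)
            img, boxes, node_px = render_raster_fixture(net, lr)
            res = capture_network(img, node_px[net.root], label_boxes=boxes)
            assert res.unresolved_paths == []
            cap = remove_through_nodes(res.network)
            assert pd.validate_network(cap) == []

    def test_deterministic(self):
        net = random_network(SimulationSpec(n=7, h=0, seed=4))
        lr = pd.compute_layout(net, optimize=False, equal_spacing=False)
        img, boxes, node_px = render_raster_fixture(net, lr)
        r1 = capture_network(img, node_px[net.root], label_boxes=boxes)
        r2 = capture_network(img, node_px[net.root], label_boxes=boxes)
        assert r1.network.edges == r2.network.edges
        assert r1.network.taxa == r2.network.taxa


class TestPostProcessing:
    def test_remove_through_node_chain(self):
        net = network_from_edges([(0, 1), (1, 2), (0, 3)],
                                 taxa={"a": 2, "b": 3})
        out = remove_through_nodes(net)
        assert out.has_edge(0, 2) and not out.has_node(1)

    def test_weights_sum_on_contraction(self):
        net = network_from_edges([(0, 1), (1, 2), (0, 3)],
                                 taxa={"a": 2, "b": 3},
                                 weights={(0, 1): 1.5, (1, 2): 2.0})
        out = remove_through_nodes(net)
        assert out.weights[(0, 2)] == 3.5

    def test_no_through_nodes_identity(self, caterpillar):
        out = remove_through_nodes(caterpillar)
        assert out.edges == caterpillar.edges

    def test_crossing_replacement_pairs_by_direction(self):
        # two straight strokes crossing at node 4: 0->4->7 (horizontal)
        # and 2->4->5 (vertical)
        net = network_from_edges(
            [(9, 0), (9, 2), (0, 4), (2, 4), (4, 5), (4, 7)],
            taxa={"a": 5, "b": 7})
        pos = {9: (0.0, -5.0), 0: (0.0, 0.0), 2: (5.0, -5.0), 4: (5.0, 0.0),
               5: (5.0, 5.0), 7: (10.0, 0.0)}
        out = replace_with_crossing(net, 4, pos)
        assert out.has_edge(0, 7) and out.has_edge(2, 5)
        assert not out.has_node(4)

    def test_crossing_requires_two_two_degree(self, caterpillar):
        with pytest.raises(ValueError):
            replace_with_crossing(caterpillar, caterpillar.root, {})

    def test_crossing_unknown_node(self, caterpillar):
        with pytest.raises(KeyError):
            replace_with_crossing(caterpillar, 99, {})

    def test_merge_broken_stroke_endpoints(self):
        net = network_from_edges([(0, 1), (2, 3), (0, 4)],
                                 taxa={"a": 3, "b": 4})
        out = merge_nodes(net, {1, 2})
        assert out.has_edge(0, 1) and out.has_edge(1, 3)

    def test_merge_two_taxa_rejected(self, two_leaf_tree):
        a = two_leaf_tree.taxa["a"]
        b = two_leaf_tree.taxa["b"]
        with pytest.raises(ValueError):
            merge_nodes(two_leaf_tree, {a, b})

    def test_merge_singleton_identity(self, caterpillar):
        out = merge_nodes(caterpillar, {caterpillar.root})
        assert out.edges == caterpillar.edges
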