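import networkx as nx
import numpy as np
import pytest

from tiptrace import (
    Centerline,
    binarize_otsu,
    contour_to_centerline,
    extract_contour,
    extrapolate_to_edge,
    orient_centerline,
    prune_to_centerline,
    voronoi_skeleton,
)
from tiptrace.centerline import SkeletonGraph, estimate_width_px
from tiptrace.segmentation import BinaryMask, Contour, resample_closed


def rectangle_contour(w=200, h=20, origin=(10.0, 10.0)):
    x0, y0 = origin
    pts = np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]])
    return Contour(points=resample_closed(pts, 1.0))


class TestVoronoiSkeleton:
    def test_rectangle_midline(self):
        c = rectangle_contour()
        sk = voronoi_skeleton(c)
        xs = sk.nodes[:, 0]
        central = (xs > 10 + 0.1 * 200) & (xs < 10 + 0.9 * 200)
        assert central.sum() > 20
        assert np.all(np.abs(sk.nodes[central, 1] - 20.0) < 1.0)

    def test_disk_degenerate(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        c = Contour(points=np.column_stack([30 + 10 * np.cos(t), 30 + 10 * np.sin(t)]))
        # medial axis of a disk is its centre: either flagged degenerate or a
        # tiny cluster of vertices at the centre
        try:
            sk = voronoi_skeleton(c)
        except ValueError:
            return
        d = np.linalg.norm(sk.nodes - [30, 30], axis=1)
        assert np.all(d < 1.0)

    def test_nodes_inside_contour(self, basic_movie):
        spec, seq, gt = basic_movie
        c = extract_contour(binarize_otsu(seq.frames[0]))
        sk = voronoi_skeleton(c)
        from shapely import contains_xy
        assert np.all(contains_xy(c.as_polygon(), sk.nodes[:, 0], sk.nodes[:, 1]))

    def test_capsule_close_to_true_axis(self, basic_movie):
        spec, seq, gt = basic_movie
        t = 0
        c = extract_contour(binarize_otsu(seq.frames[t]))
        sk = voronoi_skeleton(c)
        axis = gt.centerlines[t][1:-1]  # cap-to-cap true axis
        s = np.linalg.norm(axis - axis[0], axis=1)
        central = (s > 0.1 * s[-1]) & (s < 0.9 * s[-1])
        from scipy.spatial import cKDTree
        d, _ = cKDTree(sk.nodes).query(axis[central])
        assert d.max() < 2.0


def y_skeleton(spur_len=5.0, arm_len=100.0):
    """Hand-constructed Y graph: two long arms and one short spur at a junction."""
    g = nx.Graph()
    nodes = [np.array([0.0, 0.0])]          # 0: junction
    idx = 0
    edges = []
    for direction, length in [(np.array([1.0, 0.0]), arm_len),
                              (np.array([-1.0, 0.0]), arm_len),
                              (np.array([0.0, 1.0]), spur_len)]:
        prev = 0
        n_seg = max(int(length), 1)
        for i in range(1, n_seg + 1):
            idx += 1
            nodes.append(direction * (length * i / n_seg))
            edges.append((prev, idx))
            prev = idx
    nodes = np.array(nodes)
    for a, b in edges:
        g.add_edge(a, b, length=float(np.linalg.norm(nodes[a] - nodes[b])))
    contour = Contour(points=resample_closed(np.array(
        [[-110.0, -20.0], [110.0, -20.0], [110.0, 20.0], [-110.0, 20.0]]), 4.0))
    return SkeletonGraph(nodes=nodes, graph=g, contour=contour)


class TestPruneToCenterline:
    def test_spur_removed_path_is_two_arms(self):
        sk = y_skeleton(spur_len=5.0, arm_len=100.0)
        poly = prune_to_centerline(sk, min_branch_length=10.0, clearance_frac=0.0)
        # path spans the two long arms: endpoints at +-100 on x, spur node absent
        ends = sorted([tuple(poly[0]), tuple(poly[-1])])
        assert ends[0] == pytest.approx((-100.0, 0.0))
        assert ends[1] == pytest.approx((100.0, 0.0))
        assert not any(np.allclose(p, [0.0, 5.0]) for p in poly)

    def test_long_branch_not_removed(self):
        sk = y_skeleton(spur_len=50.0, arm_len=100.0)
        poly = prune_to_centerline(sk, min_branch_length=10.0, clearance_frac=0.0)
        assert len(poly) > 100  # both arms survive; path is still arm-to-arm

    def test_path_graph_identity(self):
        g = nx.Graph()
        nodes = np.column_stack([np.arange(10, dtype=float), np.zeros(10)])
        for i in range(9):
            g.add_edge(i, i + 1, length=1.0)
        contour = Contour(points=resample_closed(np.array(
            [[-2.0, -2.0], [12.0, -2.0], [12.0, 2.0], [-2.0, 2.0]]), 1.0))
        sk = SkeletonGraph(nodes=nodes, graph=g, contour=contour)
        poly = prune_to_centerline(sk, min_branch_length=3.0, clearance_frac=0.0)
        np.testing.assert_allclose(poly, nodes)

    def test_tie_break_deterministic(self):
        # symmetric cross: two equal-length candidate paths
        g = nx.Graph()
        nodes = np.array([[0.0, 0.0], [10.0, 0.0], [-10.0, 0.0],
                          [0.0, 10.0], [0.0, -10.0]])
        for i in (1, 2, 3, 4):
            g.add_edge(0, i, length=10.0)
        contour = Contour(points=resample_closed(np.array(
            [[-15.0, -15.0], [15.0, -15.0], [15.0, 15.0], [-15.0, 15.0]]), 2.0))
        sk = SkeletonGraph(nodes=nodes, graph=g, contour=contour)
        results = [prune_to_centerline(sk, min_branch_length=1.0, clearance_frac=0.0)
                   for _ in range(3)]
        for r in results[1:]:
            np.testing.assert_array_equal(r, results[0])
        # tie-break: endpoint list lexicographically smallest in (y, x)
        ends = sorted([tuple(results[0][0][::-1]), tuple(results[0][-1][::-1])])
        assert ends[0] == (-10.0, 0.0)

    def test_over_pruning_errors(self):
        sk = y_skeleton(spur_len=5.0, arm_len=8.0)
        with pytest.raises(ValueError, match="over-pruned|no open path"):
            prune_to_centerline(sk, min_branch_length=500.0, clearance_frac=0.0)


class TestExtrapolateToEdge:
    def test_straight_line_hits_wall_perpendicular(self):
        contour = Contour(points=resample_closed(np.array(
            [[0.0, 0.0], [100.0, 0.0], [100.0, 40.0], [0.0, 40.0]]), 1.0))
        # horizontal polyline at y=20 ending 10 px before the right wall
        poly = np.column_stack([np.arange(20.0, 91.0), np.full(71, 20.0)])
        cl = extrapolate_to_edge(poly, contour, k=5)
        # independent oracle: the ray y=20 meets the wall x=100 at (100, 20)
        np.testing.assert_allclose(cl.tip_point, [100.0, 20.0], atol=0.5)
        np.testing.assert_allclose(cl.bottom_point, [0.0, 20.0], atol=0.5)

    def test_capsule_tip_recovered(self, basic_movie):
        spec, seq, gt = basic_movie
        t = 2
        c = extract_contour(binarize_otsu(seq.frames[t]))
        sk = voronoi_skeleton(c)
        poly = prune_to_centerline(sk)
        cl = extrapolate_to_edge(poly, c, k=5, pixel_size=spec.pixel_size)
        ends = [cl.points[0], cl.points[-1]]
        d_tip = min(np.linalg.norm(e - gt.tips[t]) for e in ends)
        assert d_tip < 1.5

    def test_k_too_large_errors(self):
        contour = Contour(points=resample_closed(np.array(
            [[0.0, 0.0], [100.0, 0.0], [100.0, 40.0], [0.0, 40.0]]), 1.0))
        poly = np.column_stack([np.arange(45.0, 48.0), np.full(3, 20.0)])
        with pytest.raises(ValueError, match="k"):
            extrapolate_to_edge(poly, contour, k=10)

    def test_k_below_two_errors(self):
        contour = Contour(points=resample_closed(np.array(
            [[0.0, 0.0], [100.0, 0.0], [100.0, 40.0], [0.0, 40.0]]), 1.0))
        poly = np.column_stack([np.arange(20.0, 90.0), np.full(70, 20.0)])
        with pytest.raises(ValueError):
            extrapolate_to_edge(poly, contour, k=1)

    def test_arc_length_strictly_increasing(self, basic_movie):
        spec, seq, gt = basic_movie
        c = extract_contour(binarize_otsu(seq.frames[0]))
        cl = contour_to_centerline(c, pixel_size=spec.pixel_size, bottom_first=True)
        assert np.all(np.diff(cl.s_um) > 0)


class TestOrientCenterline:
    def _straight(self, reverse=False):
        pts = np.column_stack([np.linspace(5, 100, 40), np.linspace(5, 100, 40)])
        if reverse:
            pts = pts[::-1]
        return Centerline(points=pts, pixel_size=1.0)

    def test_anchor(self):
        cl = orient_centerline(self._straight(reverse=True), anchor=(0.0, 0.0))
        np.testing.assert_allclose(cl.bottom_point, [5.0, 5.0])
        assert cl.oriented

    def test_prev_correspondence(self):
        prev = orient_centerline(self._straight(), anchor=(0.0, 0.0))
        cur = self._straight(reverse=True)
        out = orient_centerline(cur, prev=prev)
        np.testing.assert_allclose(out.bottom_point, [5.0, 5.0])

    def test_no_information_errors(self):
        with pytest.raises(ValueError, match="orientation"):
            orient_centerline(self._straight())

    def test_explicit_choice(self):
        out = orient_centerline(self._straight(), bottom_first=False)
        np.testing.assert_allclose(out.bottom_point, [100.0, 100.0])


class TestProperties:
    @pytest.mark.parametrize("width_px,length_px,bend", [
        (10, 60, 0.0), (20, 150, 10.0), (40, 300, 20.0), (14, 100, 30.0)])
    def test_length_accuracy(self, capsule_factory, width_px, length_px, bend):
        px = 0.5
        n = 5
        shape = (int(length_px * 1.4) + 60, int(length_px * 1.2) + 60)
        spec, seq, gt = capsule_factory(
            n_frames=n, width=width_px * px, initial_length=length_px * px,
            growth_rate=1.0, bend_rate=bend / n, frame_shape=shape, pixel_size=px,
            seed=21)
        for t in (0, n - 1):
            c = extract_contour(binarize_otsu(seq.frames[t]))
            cl = contour_to_centerline(c, pixel_size=px, anchor=tuple(gt.bottoms[t]))
            tol = max(2 * px, 0.02 * gt.lengths_um[t])
            assert abs(cl.length_um - gt.lengths_um[t]) <= tol

    def test_rotation_invariance(self, basic_movie):
        from tiptrace.register import RigidTransform, transform_frame, transform_points, invert
        spec, seq, gt = basic_movie
        frame = seq.frames[0]
        c0 = extract_contour(binarize_otsu(frame))
        cl0 = contour_to_centerline(c0, pixel_size=spec.pixel_size,
                                    anchor=tuple(gt.bottoms[0]))
        theta = 27.0
        t = RigidTransform(theta=theta)
        rotated = transform_frame(frame, t)
        c1 = extract_contour(binarize_otsu(rotated))
        # a point at p in the original appears at W_t(p) in the warped image
        anchor_rot = transform_points(gt.bottoms[0], t, frame.shape)[0]
        cl1 = contour_to_centerline(c1, pixel_size=spec.pixel_size,
                                    anchor=tuple(anchor_rot))
        # map measured endpoints back to original coordinates and compare
        tip_back = transform_points(cl1.tip_point, invert(t), frame.shape)[0]
        bot_back = transform_points(cl1.bottom_point, invert(t), frame.shape)[0]
        assert np.linalg.norm(tip_back - cl0.tip_point) < 1.0
        assert np.linalg.norm(bot_back - cl0.bottom_point) < 1.0

    def test_voronoi_matches_distance_transform_ridge(self, basic_movie):
        """Independent oracle: maximal-inscribed-disk ridge from the distance map."""
        from skimage.morphology import medial_axis
        spec, seq, gt = basic_movie
        mask = binarize_otsu(seq.frames[0])
        c = extract_contour(mask)
        sk = voronoi_skeleton(c)
        poly = prune_to_centerline(sk)
        ridge, dist = medial_axis(mask.grid, return_distance=True)
        # keep ridge pixels with substantial clearance (drop its own cap spurs)
        rr, cc = np.nonzero(ridge & (dist > 0.6 * dist.max()))
        ridge_xy = np.column_stack([cc, rr]).astype(float)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(ridge_xy).query(poly)
        assert d.mean() < 1.0


class TestWidthEstimate:
    def test_capsule_width(self, basic_movie):
        spec, seq, gt = basic_movie
        c = extract_contour(binarize_otsu(seq.frames[0]))
        sk = voronoi_skeleton(c)
        w = estimate_width_px(sk) * spec.pixel_size
        assert w == pytest.approx(spec.width, rel=0.35)
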