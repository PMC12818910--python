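"""Centerline extraction by Voronoi skeletonization of the cell contour.

The Voronoi diagram of a densely, uniformly sampled boundary approximates
the medial axis: vertices falling inside the polygon sketch the skeleton.
Side branches (from boundary noise and from the rounded cap corners) are
pruned by iteratively removing short leaf branches; the centerline is the
longest remaining geodesic between two leaf nodes. Tip and bottom are then
found by fitting a total-least-squares line through the terminal skeleton
points at each end and intersecting the outward ray with the contour.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import Voronoi, cKDTree
from shapely import contains_xy
from shapely.geometry import LineString, Point
from statsmodels.nonparametric.smoothers_lowess import lowess

from tiptrace.segmentation import Contour
from tiptrace.types import polyline_arclength


@dataclass
class SkeletonGraph:
    """Interior Voronoi skeleton: nodes are (x, y) vertices, edges weighted by length."""

    nodes: np.ndarray          # (M, 2)
    graph: nx.Graph            # node indices into `nodes`, edge attr "length"
    contour: Contour

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(self.graph.edges)


@dataclass
class Centerline:
    """Ordered polyline from bottom to tip, arc-length parameterized.

    The first and last points lie ON the contour (extrapolated endpoints);
    interior points are skeleton vertices strictly inside the cell.
    """

    points: np.ndarray
    pixel_size: float
    frame_index: int = 0
    oriented: bool = False     # True once bottom/tip assignment is established

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        seg = np.hypot(*np.diff(self.points, axis=0).T)
        if np.any(seg <= 0):
            keep = np.concatenate([[True], seg > 0])
            self.points = self.points[keep]

    @property
    def s_px(self) -> np.ndarray:
        return polyline_arclength(self.points)

    @property
    def s_um(self) -> np.ndarray:
        return self.s_px * self.pixel_size

    @property
    def length_um(self) -> float:
        return float(self.s_um[-1])

    @property
    def bottom_point(self) -> np.ndarray:
        return self.points[0]

    @property
    def tip_point(self) -> np.ndarray:
        return self.points[-1]

    def reversed(self) -> "Centerline":
        return Centerline(points=self.points[::-1].copy(), pixel_size=self.pixel_size,
                          frame_index=self.frame_index, oriented=self.oriented)


def voronoi_skeleton(contour: Contour) -> SkeletonGraph:
    """Voronoi skeleton of the contour point cloud.

    Keeps Voronoi vertices strictly inside the polygon and finite Voronoi
    edges whose both endpoints are kept; returns the largest connected
    component.
    """
    pts = contour.points
    vor = Voronoi(pts)
    poly = contour.as_polygon()
    inside = contains_xy(poly, vor.vertices[:, 0], vor.vertices[:, 1])
    if inside.sum() < 2:
        raise ValueError("degenerate skeleton: fewer than 2 interior Voronoi vertices")

    g = nx.Graph()
    for v0, v1 in vor.ridge_vertices:
        if v0 < 0 or v1 < 0 or not (inside[v0] and inside[v1]):
            continue
        w = float(np.linalg.norm(vor.vertices[v0] - vor.vertices[v1]))
        g.add_edge(v0, v1, length=w)
    if g.number_of_nodes() < 2:
        raise ValueError("degenerate skeleton: no interior Voronoi edges")
    largest = max(nx.connected_components(g), key=len)
    g = g.subgraph(largest).copy()

    keep = sorted(g.nodes)
    remap = {old: i for i, old in enumerate(keep)}
    nodes = vor.vertices[keep]
    g2 = nx.Graph()
    g2.add_nodes_from(range(len(keep)))
    for a, b, data in g.edges(data=True):
        g2.add_edge(remap[a], remap[b], **data)
    return SkeletonGraph(nodes=nodes, graph=g2, contour=contour)


def estimate_width_px(skeleton: SkeletonGraph) -> float:
    """Cell width estimate: 2x mean distance from skeleton nodes to the contour."""
    tree = cKDTree(skeleton.contour.points)
    d, _ = tree.query(skeleton.nodes)
    return 2.0 * float(np.mean(d))


def _leaf_branch(g: nx.Graph, leaf: int) -> tuple[list[int], float]:
    """Walk from a degree-1 node to the nearest junction (degree >= 3) or other leaf."""
    path = [leaf]
    length = 0.0
    prev, cur = None, leaf
    while True:
        nbrs = [n for n in g.neighbors(cur) if n != prev]
        if not nbrs or g.degree(cur) >= 3:
            break
        nxt = nbrs[0]
        length += g.edges[cur, nxt]["length"]
        path.append(nxt)
        prev, cur = cur, nxt
        if g.degree(cur) != 2:
            break
    return path, length


def prune_to_centerline(skeleton: SkeletonGraph,
                        min_branch_length: float | None = None,
                        clearance_frac: float = 0.8) -> np.ndarray:
    """Prune spur branches, then take the longest leaf-to-leaf geodesic.

    Two filters make the centerline one that "does not reach the contour":
    nodes whose clearance (distance to the contour) falls below
    ``clearance_frac`` times the median node clearance are dropped, and
    remaining leaf branches shorter than ``min_branch_length`` (default:
    half the estimated cell width — spurs caused by boundary noise are
    shorter than the half-width) are removed iteratively.
    Returns the ordered (N, 2) polyline (orientation arbitrary).
    """
    if min_branch_length is None:
        min_branch_length = estimate_width_px(skeleton) / 2.0
    g = skeleton.graph.copy()
    nodes = skeleton.nodes

    if clearance_frac > 0:
        tree = cKDTree(skeleton.contour.points)
        clearance, _ = tree.query(nodes)
        node_ids = np.fromiter(g.nodes, dtype=int)
        median_clear = float(np.median(clearance[node_ids]))
        low = [n for n in node_ids if clearance[n] < clearance_frac * median_clear]
        g.remove_nodes_from(low)
        if g.number_of_edges() == 0:
            raise ValueError("over-pruned; reduce clearance_frac")
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()

    changed = True
    while changed:
        changed = False
        # collect all short leaf branches against the pass-start graph, then
        # remove them together: sequential removal would merge one of two
        # sibling spurs (e.g. at a rounded cap fork) into the trunk
        doomed: set[int] = set()
        for leaf in [n for n in g.nodes if g.degree(n) == 1]:
            path, length = _leaf_branch(g, leaf)
            # only prune branches hanging off a junction, never the trunk itself
            if length < min_branch_length and g.degree(path[-1]) >= 3:
                doomed.update(path[:-1])
        if doomed:
            g.remove_nodes_from(doomed)
            changed = True
        if g.number_of_nodes() == 0:
            raise ValueError("over-pruned; reduce min_branch_length")

    if g.number_of_edges() == 0:
        raise ValueError("over-pruned; reduce min_branch_length")
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    leaves = [n for n in g.nodes if g.degree(n) == 1]
    if len(leaves) < 2:
        # cycle without leaves cannot define a centerline
        raise ValueError("skeleton has no open path; degenerate (near-circular) cell")

    best = None
    for src in leaves:
        dist, paths = nx.single_source_dijkstra(g, src, weight="length")
        for dst in leaves:
            if dst == src or dst not in dist:
                continue
            key = (-dist[dst],)
            path = paths[dst]
            ends = sorted([tuple(nodes[path[0]][::-1]), tuple(nodes[path[-1]][::-1])])
            cand = (key + (ends,), path)
            if best is None or cand[0] < best[0]:
                best = cand
    path = best[1]
    pts = nodes[path]

    # trim path ends whose clearance falls below the typical trunk clearance:
    # inside the rounded caps the sampled medial axis is unreliable, and the
    # linear extrapolation should start from the well-defined tube region
    if clearance_frac > 0 and len(pts) > 6:
        tree = cKDTree(skeleton.contour.points)
        clear, _ = tree.query(pts)
        med = float(np.median(clear))
        cut_level = 0.93 * med
        s = polyline_arclength(pts)
        lo_cut = 0
        while (lo_cut < len(pts) - 6 and clear[lo_cut] < cut_level
               and s[lo_cut] < med):
            lo_cut += 1
        hi_cut = len(pts)
        while (hi_cut > lo_cut + 6 and clear[hi_cut - 1] < cut_level
               and s[-1] - s[hi_cut - 1] < med):
            hi_cut -= 1
        pts = pts[lo_cut:hi_cut]

    # deterministic orientation of the raw polyline: start at the (y, x)-smaller end
    if tuple(pts[-1][::-1]) < tuple(pts[0][::-1]):
        pts = pts[::-1]
    return pts.copy()


def smooth_polyline(points: np.ndarray, frac: float = 0.2) -> np.ndarray:
    """Lowess smoothing of an open polyline against its arc length."""
    s = polyline_arclength(points)
    x = lowess(points[:, 0], s, frac=frac, it=0, return_sorted=False)
    y = lowess(points[:, 1], s, frac=frac, it=0, return_sorted=False)
    return np.column_stack([x, y])


def _tls_direction(pts: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction (unit vector) through points."""
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])


def resample_open(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample an open polyline to uniform arc-length spacing (endpoints kept)."""
    pts = np.asarray(points, dtype=float)
    s = polyline_arclength(pts)
    n = max(int(round(s[-1] / spacing)), 2)
    s_new = np.linspace(0.0, s[-1], n + 1)
    x = np.interp(s_new, s, pts[:, 0])
    y = np.interp(s_new, s, pts[:, 1])
    return np.column_stack([x, y])


def _robust_tls(term: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """TLS line (direction, centroid) with orthogonal-residual outlier rejection.

    Terminal skeleton points inside the rounded cap can wander laterally;
    two reweighting passes keep the fit anchored on the stable tube portion.
    """
    pts = term
    d = _tls_direction(pts)
    c = pts.mean(axis=0)
    for _ in range(2):
        normal = np.array([-d[1], d[0]])
        resid = (term - c) @ normal
        mad = np.median(np.abs(resid - np.median(resid)))
        tol = max(2.5 * mad, 0.15)
        keep = np.abs(resid - np.median(resid)) <= tol
        if keep.sum() < max(3, len(term) // 2) or keep.all():
            break
        pts = term[keep]
        d = _tls_direction(pts)
        c = pts.mean(axis=0)
    return d, c


def _extend_end(polyline: np.ndarray, contour: Contour, k: int, at_start: bool,
                end_offset: int = 0) -> np.ndarray:
    # skip the last end_offset points: the skeleton is least reliable right
    # where it enters the cap region
    if end_offset > 0 and len(polyline) >= k + end_offset + 2:
        polyline = polyline[end_offset:] if at_start else polyline[:-end_offset]
    term = polyline[:k][::-1] if at_start else polyline[-k:]
    # outward = from the k-th-from-end point toward the terminal point
    d, centroid = _robust_tls(term)
    outward = term[-1] - term[0]
    if np.dot(d, outward) < 0:
        d = -d
    # project the terminal point onto the fitted line before casting the ray
    end_pt = centroid + np.dot(term[-1] - centroid, d) * d

    bounds = contour.points
    diameter = float(np.hypot(*(bounds.max(axis=0) - bounds.min(axis=0))))
    ray = LineString([end_pt, end_pt + d * 2.0 * diameter])
    boundary = contour.as_polygon().exterior
    hit = ray.intersection(boundary)
    if hit.is_empty:
        raise ValueError("extrapolation escaped contour: ray does not hit the boundary")
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append((geom.x, geom.y))
        else:
            pts.extend(list(geom.coords))
    pts = np.array(pts)
    dists = np.linalg.norm(pts - end_pt, axis=1)
    return pts[np.argmin(dists)]


def extrapolate_to_edge(polyline: np.ndarray, contour: Contour, k: int = 5,
                        pixel_size: float = 1.0, frame_index: int = 0) -> Centerline:
    """Extend both ends of the pruned skeleton to the cell edge.

    At each end a total-least-squares line is fitted through the ``k``
    terminal points and extended outward; the endpoint is the nearest
    intersection of that ray with the contour polygon.
    """
    polyline = np.asarray(polyline, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(polyline) < k:
        raise ValueError(f"polyline has {len(polyline)} points; k={k} required per end")
    # uniform 1-px resampling so the k terminal points span ~k px of arc
    # length regardless of local Voronoi vertex density
    uniform = resample_open(polyline, spacing=1.0)
    if len(uniform) < k:
        uniform = polyline
    start_pt = _extend_end(uniform, contour, k, at_start=True)
    end_pt = _extend_end(uniform, contour, k, at_start=False)
    pts = np.vstack([start_pt, polyline, end_pt])
    return Centerline(points=pts, pixel_size=pixel_size, frame_index=frame_index)


def orient_centerline(centerline: Centerline,
                      prev: Centerline | None = None,
                      anchor: tuple[float, float] | None = None,
                      bottom_first: bool | None = None) -> Centerline:
    """Assign which end is the bottom.

    Priority: explicit ``anchor`` point (the end nearer it becomes the
    bottom); else ``prev`` frame's oriented centerline (nearest-endpoint
    correspondence); else an explicit ``bottom_first`` choice for frame 0.
    """
    a, b = centerline.points[0], centerline.points[-1]
    if anchor is not None:
        anchor = np.asarray(anchor, dtype=float)
        flip = np.linalg.norm(b - anchor) < np.linalg.norm(a - anchor)
    elif prev is not None:
        if not prev.oriented:
            raise ValueError("previous centerline is not oriented")
        d_ab = np.linalg.norm(a - prev.bottom_point) + np.linalg.norm(b - prev.tip_point)
        d_ba = np.linalg.norm(a - prev.tip_point) + np.linalg.norm(b - prev.bottom_point)
        if np.isclose(d_ab, d_ba):
            raise ValueError("ambiguous orientation: both ends equidistant from previous")
        flip = d_ba < d_ab
    elif bottom_first is not None:
        flip = not bottom_first
    else:
        raise ValueError("orientation undetermined: provide anchor, prev, or bottom_first")
    out = centerline.reversed() if flip else Centerline(
        points=centerline.points.copy(), pixel_size=centerline.pixel_size,
        frame_index=centerline.frame_index)
    out.oriented = True
    return out


def contour_to_centerline(contour: Contour, pixel_size: float = 1.0,
                          min_branch_length: float | None = None,
                          k: int | None = None, smooth_frac: float | None = None,
                          prev: Centerline | None = None,
                          anchor: tuple[float, float] | None = None,
                          bottom_first: bool | None = None,
                          frame_index: int = 0) -> Centerline:
    """Full chain: Voronoi skeleton -> prune -> (smooth) -> extrapolate -> orient.

    ``k=None`` scales the extrapolation window with the cell: 0.6x the
    estimated half-width in px, floored at 10 (wide cells extrapolate farther
    and need a longer lever arm).
    """
    skel = voronoi_skeleton(contour)
    poly = prune_to_centerline(skel, min_branch_length=min_branch_length)
    if smooth_frac:
        poly = smooth_polyline(poly, frac=smooth_frac)
    if k is None:
        k = max(10, int(round(0.6 * estimate_width_px(skel) / 2.0)))
        k = min(k, max(len(poly), 2))
    cl = extrapolate_to_edge(poly, contour, k=k, pixel_size=pixel_size,
                             frame_index=frame_index)
    return orient_centerline(cl, prev=prev, anchor=anchor, bottom_first=bottom_first)
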