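"""Embedding exactness, stress minimization and polygon geometry."""

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point

from metalocus.contacts import DistanceGraph, build_distance_graph, \
    transform_and_select
from metalocus.layout import (build_gaudi, compute_layout, layout_stress,
                              mean_consecutive_step)
from metalocus.synth import make_locus


def graph_from_edges(edges):
    g = nx.Graph()
    for a, b, d in edges:
        g.add_edge(a, b, distance=d)
    return DistanceGraph(region=None, graph=g, backbone_strength=1.0)


class TestComputeLayout:
    def test_equilateral_triangle_embedded_exactly(self):
        d = 0.7
        dg = graph_from_edges([(0, 1, d), (0, 2, d), (1, 2, d)])
        bins, P = compute_layout(dg)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert np.linalg.norm(P[i] - P[j]) == pytest.approx(d, abs=1e-6)

    def test_uniform_chain_has_uniform_steps(self):
        dg = graph_from_edges([(i, i + 1, 0.3) for i in range(9)])
        _, P = compute_layout(dg)
        steps = np.linalg.norm(np.diff(P, axis=0), axis=1)
        assert steps.std() / steps.mean() < 0.05

    def test_stress_not_worse_than_circular_init(self, hub_locus):
        cm, _, _ = hub_locus
        dg = build_distance_graph(transform_and_select(cm, 1.0))
        bins, P = compute_layout(dg)
        n = len(bins)
        theta = 2 * np.pi * np.arange(n) / n
        circ = np.column_stack([np.cos(theta), np.sin(theta)])
        assert layout_stress(dg, bins, P) <= layout_stress(dg, bins, circ)

    def test_deterministic(self, hub_locus):
        cm, _, _ = hub_locus
        dg = build_distance_graph(transform_and_select(cm, 1.0))
        _, P1 = compute_layout(dg, seed=0)
        _, P2 = compute_layout(dg, seed=0)
        np.testing.assert_array_equal(P1, P2)

    def test_disconnected_graph_rejected(self):
        dg = graph_from_edges([(0, 1, 1.0), (2, 3, 1.0)])
        with pytest.raises(ValueError, match="disconnected"):
            compute_layout(dg)

    def test_nonpositive_distance_rejected(self):
        dg = graph_from_edges([(0, 1, 1.0), (1, 2, 0.0)])
        with pytest.raises(ValueError, match="non-finite or non-positive"):
            compute_layout(dg)


class TestBuildGaudi:
    def test_unit_square_symmetry(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        gl = build_gaudi(pts)
        areas = [p.area for p in gl.polygons]
        assert np.ptp(areas) < 1e-9 * max(areas)
        center = np.array([0.5, 0.5])
        for k, poly in enumerate(gl.polygons):
            # each polygon stays in its corner's quadrant of the plane
            cx, cy = np.asarray(poly.centroid.coords[0])
            assert np.sign(cx - center[0]) == np.sign(pts[k, 0] - center[0])
            assert np.sign(cy - center[1]) == np.sign(pts[k, 1] - center[1])

    def test_polygon_contracts(self, hub_locus):
        cm, _, _ = hub_locus
        dg = build_distance_graph(transform_and_select(cm, 1.0))
        bins, P = compute_layout(dg)
        gl = build_gaudi(P, bins=bins, region=cm.region)
        assert len(gl.polygons) == len(bins)
        assert gl.buffer_distance == pytest.approx(1.5 * gl.mean_step)
        total_area = 0.0
        for k, poly in enumerate(gl.polygons):
            assert poly.is_valid and poly.area > 0
            # polygon contained in its buffer disk (finite by construction)
            disk = Point(P[k]).buffer(gl.buffer_distance * (1 + 1e-9),
                                      quad_segs=64)
            assert disk.contains(poly) or disk.covers(poly)
            assert poly.covers(Point(P[k])) or poly.distance(Point(P[k])) < 1e-9
            total_area += poly.area
        assert total_area <= len(bins) * np.pi * gl.buffer_distance**2

    def test_polygons_have_disjoint_interiors(self, hub_locus):
        cm, _, _ = hub_locus
        dg = build_distance_graph(transform_and_select(cm, 1.0))
        bins, P = compute_layout(dg)
        gl = build_gaudi(P, bins=bins)
        rng = np.random.default_rng(0)
        pick = rng.choice(len(bins), size=25, replace=False)
        for a in pick[:5]:
            for b in pick:
                if a == b:
                    continue
                inter = gl.polygons[a].intersection(gl.polygons[b])
                assert inter.area < 1e-9 * gl.polygons[a].area

    def test_dummy_generators_outside_all_buffer_disks(self):
        rng = np.random.default_rng(4)
        pts = rng.random((30, 2)) * 3
        gl = build_gaudi(pts)
        lo = pts.min(axis=0) - 2 * gl.buffer_distance
        hi = pts.max(axis=0) + 2 * gl.buffer_distance
        cx, cy = (lo + hi) / 2
        dummies = np.array([[lo[0], lo[1]], [cx, lo[1]], [hi[0], lo[1]],
                            [hi[0], cy], [hi[0], hi[1]], [cx, hi[1]],
                            [lo[0], hi[1]], [lo[0], cy]])
        dmin = np.min(np.linalg.norm(pts[None, :, :] - dummies[:, None, :],
                                     axis=2))
        assert dmin > gl.buffer_distance

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_gaudi(np.array([[0.0, 0], [1, 1]]))
        with pytest.raises(ValueError, match="collinear"):
            build_gaudi(np.column_stack([np.arange(5.0), np.arange(5.0)]))


def test_mean_step_skips_gaps():
    bins = np.array([0, 1, 2, 5, 6])
    coords = np.column_stack([np.array([0.0, 1, 2, 9, 10]), np.zeros(5)])
    # consecutive-in-sequence pairs: (0,1),(1,2),(5,6) -> steps 1,1,1
    assert mean_consecutive_step(bins, coords) == pytest.approx(1.0)


def test_rigid_motion_preserves_geometry_statistics(hub_locus):
    """Rotation + translation leaves neighbor sets and LMI unchanged."""
    from metalocus.signals import attach_signal
    from metalocus.spatial import build_weights, local_moran

    cm, sig, _ = hub_locus
    dg = build_distance_graph(transform_and_select(cm, 1.0))
    bins, P = compute_layout(dg)
    ang = 0.73
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    P2 = P @ R.T + np.array([5.0, -3.0])
    res = {}
    for tag, coords in [("orig", P), ("moved", P2)]:
        gl = attach_signal(build_gaudi(coords, bins=bins, region=cm.region),
                           sig)
        w = build_weights(gl)
        res[tag] = (w, local_moran(gl.signal, w))
    for k in range(res["orig"][0].n):
        assert set(res["orig"][0].neighbors[k]) == set(res["moved"][0].neighbors[k])
    np.testing.assert_allclose(res["orig"][1]["lmi"], res["moved"][1]["lmi"],
                               atol=1e-9)
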