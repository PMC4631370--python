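"""Road-graph construction, snapping and service-area tests."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import LineString, Point

from emaccess.roadnet import (
    NetworkLocation,
    SnapError,
    build_network,
    buffer_service_area,
    service_area,
    snap_point,
)

from .conftest import random_network, random_segments
from .oracles import brute_nearest, brute_planarize, in_intervals, lattice_distances


class TestBuildNetwork:
    def test_x_crossing_becomes_a_node(self):
        net = build_network([
            LineString([(0, 0), (100, 100)]),
            LineString([(0, 100), (100, 0)]),
        ])
        assert net.n_nodes == 5 and net.n_edges == 4

    def test_single_straight_segment(self):
        net = build_network([LineString([(0, 0), (10_000, 0)])])
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.edge_data(0)["length_m"] == pytest.approx(10_000.0)

    def test_lengths_match_geometry(self, rng):
        net = random_network(rng, 25)
        for eid in range(net.n_edges):
            d = net.edge_data(eid)
            assert d["length_m"] == pytest.approx(d["geometry"].length,
                                                  rel=1e-6)

    def test_endpoint_snapping_merges_nodes(self):
        net = build_network(
            [LineString([(0, 0), (100, 0)]),
             LineString([(100.4, 0.3), (200, 0)])],
            snap_tol_m=1.0,
        )
        assert net.n_nodes == 3 and net.n_edges == 2

    @pytest.mark.parametrize("n_segments", [20, 50])
    def test_random_scribble_matches_pairwise_splitter(self, rng, n_segments):
        """Node/edge counts equal the O(n²) intersection oracle."""
        segs = random_segments(rng, n_segments, 2000.0)
        net = build_network([LineString([a, b]) for a, b in segs],
                            snap_tol_m=1e-6)
        n_nodes, n_edges = brute_planarize(segs)
        assert (net.n_nodes, net.n_edges) == (n_nodes, n_edges)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network([])

    def test_component_labels(self):
        net = build_network([
            LineString([(0, 0), (100, 0)]),
            LineString([(5000, 0), (5100, 0)]),
        ])
        labels = net.component_labels()
        assert len(set(labels.values())) == 2


class TestSnapPoint:
    def test_point_on_edge_midpoint(self):
        net = build_network([LineString([(0, 0), (1000, 0)])])
        loc = snap_point(net, Point(500, 0))
        assert loc.offset_m == pytest.approx(500.0)
        assert loc.snap_distance_m == pytest.approx(0.0)

    def test_equidistant_tie_breaks_to_lowest_edge_id(self):
        net = build_network([
            LineString([(0, 100), (1000, 100)]),
            LineString([(0, -100), (1000, -100)]),
        ])
        loc = snap_point(net, Point(500, 0))
        assert loc.edge_id == 0

    def test_failure_beyond_max_snap(self):
        net = build_network([LineString([(0, 0), (100, 0)])])
        with pytest.raises(SnapError):
            snap_point(net, Point(0, 10_000), max_snap_m=5000)

    def test_random_points_match_exhaustive_search(self, rng):
        """100 random points agree with the numpy nearest-point oracle."""
        net = random_network(rng, 30)
        coord_lists = [list(g.coords) for g in net.edge_geometries()]
        for _ in range(100):
            p = rng.uniform(-200, 2200, size=2)
            loc = snap_point(net, Point(*p), max_snap_m=1e9)
            ei, off, dist = brute_nearest(coord_lists, p)
            assert loc.snap_distance_m == pytest.approx(dist, abs=1e-6)
            assert loc.edge_id == ei
            assert loc.offset_m == pytest.approx(off, abs=1e-6)


class TestServiceArea:
    def _line_net(self):
        return build_network([LineString([(0, 0), (10_000, 0)])])

    def test_cutoff_zero_gives_source_points_only(self):
        net = self._line_net()
        src = snap_point(net, Point(4000, 0))
        sa = service_area(net, [src], 0.0)
        geom = sa.geometry
        assert geom.geom_type in ("Point", "MultiPoint")
        assert geom.distance(Point(4000, 0)) < 1e-9

    def test_linear_half_coverage(self):
        net = self._line_net()
        src = snap_point(net, Point(0, 0))
        sa = service_area(net, [src], 5000.0)
        geom = sa.geometry
        assert geom.length == pytest.approx(5000.0)
        assert geom.bounds == pytest.approx((0, 0, 5000, 0))

    def test_mid_edge_source_reaches_both_ways(self):
        net = self._line_net()
        src = snap_point(net, Point(4000, 0))
        sa = service_area(net, [src], 1000.0)
        assert sa.geometry.bounds == pytest.approx((3000, 0, 5000, 0))

    def test_toy_cycle_with_truncated_edges_matches_oracle(self):
        """A cycle whose far edges are partially reached: interval membership
        equals the dense-sampling Dijkstra oracle everywhere."""
        square = [
            LineString([(0, 0), (1000, 0)]),
            LineString([(1000, 0), (1000, 1000)]),
            LineString([(1000, 1000), (0, 1000)]),
            LineString([(0, 1000), (0, 0)]),
            LineString([(1000, 0), (2500, 0)]),   # spur
            LineString([(0, 1000), (0, 2500)]),   # spur
        ]
        net = build_network(square)
        src = snap_point(net, Point(0, 0))
        cutoff = 1600.0
        sa = service_area(net, [src], cutoff)
        for entry in lattice_distances(net, [src], step_m=1.0):
            ivs = sa.intervals.get(entry["edge_id"], [])
            for t, d in zip(entry["ts"], entry["dists"]):
                if abs(d - cutoff) <= 1.0:
                    continue
                assert in_intervals(t, ivs) == (d <= cutoff)

    def test_unreachable_component_excluded(self):
        net = build_network([
            LineString([(0, 0), (1000, 0)]),
            LineString([(50_000, 0), (51_000, 0)]),
        ])
        src = snap_point(net, Point(0, 0))
        sa = service_area(net, [src], 5000.0)
        reached_eids = set(sa.intervals)
        far_eid = next(
            eid for eid in range(net.n_edges)
            if net.edge_data(eid)["geometry"].bounds[0] >= 49_000
        )
        assert far_eid not in reached_eids

    def test_cutoff_monotonicity_and_union_property(self, rng):
        """reached(r1) ⊆ reached(r2) for r1 ≤ r2, and the service area of a
        pooled source set is the union of the individual areas."""
        net = random_network(rng, 30)
        for _ in range(20):
            pts = rng.uniform(0, 2000, size=(2, 2))
            s1 = snap_point(net, Point(*pts[0]), max_snap_m=1e9)
            s2 = snap_point(net, Point(*pts[1]), max_snap_m=1e9)
            r1, r2 = sorted(rng.uniform(100, 2500, size=2))

            a_small = service_area(net, [s1], r1)
            a_big = service_area(net, [s1], r2)
            for eid, ivs in a_small.intervals.items():
                big = a_big.intervals.get(eid, [])
                for a, b in ivs:
                    assert in_intervals(a, big, 1e-6)
                    assert in_intervals(b, big, 1e-6)
                    assert in_intervals(0.5 * (a + b), big, 1e-6)

            pooled = service_area(net, [s1, s2], r1)
            ind1 = service_area(net, [s1], r1)
            ind2 = service_area(net, [s2], r1)
            for eid in set(pooled.intervals) | set(ind1.intervals) | set(ind2.intervals):
                merged = ind1.intervals.get(eid, []) + ind2.intervals.get(eid, [])
                pooled_ivs = pooled.intervals.get(eid, [])
                length = net.edge_data(eid)["length_m"]
                for t in np.linspace(0, length, 50):
                    assert in_intervals(t, pooled_ivs, 1e-6) == in_intervals(
                        t, merged, 1e-6
                    )

    def test_euclidean_containment(self, rng):
        """Network distance dominates straight-line distance, so the reached
        geometry lies inside the union of Euclidean disks of radius r."""
        net = random_network(rng, 25)
        src = snap_point(net, Point(*rng.uniform(0, 2000, 2)), max_snap_m=1e9)
        cutoff = 900.0
        sa = service_area(net, [src], cutoff)
        disk = net.locate(src).buffer(cutoff * 1.001)
        geom = sa.geometry
        if not geom.is_empty:
            assert disk.covers(geom)


class TestBuffer:
    def test_stadium_area(self):
        net = build_network([LineString([(0, 0), (1000, 0)])])
        sa = service_area(net, [snap_point(net, Point(0, 0))], 1000.0)
        poly = buffer_service_area(sa, 100.0)
        expected = 2 * 1000 * 100 + math.pi * 100**2
        assert poly.area == pytest.approx(expected, rel=0.005)

    def test_empty_area_buffers_to_empty_polygon(self):
        net = build_network([LineString([(0, 0), (1000, 0)])])
        sa = service_area(net, [snap_point(net, Point(500, 0))], 0.0)
        sa.intervals.clear()
        sa.source_points.clear()
        assert buffer_service_area(sa, 100.0).is_empty

    def test_buffer_contains_reached_vertices(self, rng):
        net = random_network(rng, 20)
        src = snap_point(net, Point(1000, 1000), max_snap_m=1e9)
        sa = service_area(net, [src], 800.0)
        poly = buffer_service_area(sa, 50.0)
        geom = sa.geometry
        for x, y in shapely.get_coordinates(geom):
            assert poly.covers(Point(x, y))


def test_random_graphs_match_dense_sampling_oracle(rng):
    """Cross-check interval extraction on random planarized scribbles."""
    for _ in range(5):
        net = random_network(rng, 25)
        pts = rng.uniform(0, 2000, size=(2, 2))
        sources = [snap_point(net, Point(*p), max_snap_m=1e9) for p in pts]
        cutoff = float(rng.uniform(300, 1500))
        sa = service_area(net, sources, cutoff)
        for entry in lattice_distances(net, sources, step_m=2.0):
            ivs = sa.intervals.get(entry["edge_id"], [])
            for t, d in zip(entry["ts"], entry["dists"]):
                if abs(d - cutoff) <= 2.0:
                    continue
                assert in_intervals(t, ivs) == (d <= cutoff)
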