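"""Planarized road graphs and network-distance service areas.

A raw digitized road layer is a bag of polylines whose crossings need not be
graph nodes.  :func:`build_network` corrects the topology so every
intersection is an endpoint node (planarization), merges endpoints within a
snap tolerance, and yields a routable undirected graph whose edges carry
their polyline geometry and arc length in meters.

A *service area* at cutoff ``r`` is the portion of the network reachable
within network distance ``r`` of a set of source locations: whole edges where
the interior stays within ``r``, and partial edges truncated by arc-length
interpolation where the cutoff falls mid-edge.  Coverage is distance-based
and undirected — no travel-time costing, one-way streets or turn penalties.

All coordinates are planar meters in a projected CRS; projecting is the
caller's responsibility.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiLineString, Point
from shapely.ops import substring, unary_union

logger = logging.getLogger(__name__)

__all__ = [
    "RoadNetwork",
    "NetworkLocation",
    "ServiceArea",
    "SnapError",
    "build_network",
    "snap_point",
    "service_area",
    "buffer_service_area",
]


class SnapError(ValueError):
    """A point could not be attached to the network within max_snap_m."""


@dataclass(frozen=True)
class NetworkLocation:
    """A point attached to the network: an edge id plus arc-length offset
    from the edge's first node, and how far the original point was moved."""

    edge_id: int
    offset_m: float
    snap_distance_m: float


@dataclass
class RoadNetwork:
    """Planarized, routable road graph.

    ``graph`` is an undirected :class:`networkx.MultiGraph`; node attributes
    hold ``(x, y)`` positions, edge attributes ``geometry`` (LineString),
    ``length_m`` and ``edge_id``.  ``edge_index[edge_id]`` gives
    ``(u, v, key)``; edge ids are assigned deterministically (sorted WKB) so
    tie-breaks are reproducible.
    """

    graph: nx.MultiGraph
    edge_index: list[tuple[int, int, int]] = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_data(self, edge_id: int) -> dict:
        u, v, k = self.edge_index[edge_id]
        return self.graph.edges[u, v, k]

    def edge_geometries(self) -> list[LineString]:
        return [self.edge_data(i)["geometry"] for i in range(self.n_edges)]

    def component_labels(self) -> dict[int, int]:
        """node id -> connected-component label (0-based, by smallest node)."""
        labels = {}
        for i, comp in enumerate(
            sorted(nx.connected_components(self.graph), key=min)
        ):
            for n in comp:
                labels[n] = i
        return labels

    def locate(self, location: NetworkLocation) -> Point:
        """The planar point a :class:`NetworkLocation` refers to."""
        return self.edge_data(location.edge_id)["geometry"].interpolate(
            location.offset_m
        )


def _as_linestrings(segments: Iterable) -> list[LineString]:
    out: list[LineString] = []
    for seg in segments:
        if isinstance(seg, LineString):
            out.append(seg)
        elif isinstance(seg, MultiLineString):
            out.extend(seg.geoms)
        else:
            out.append(LineString(seg))
    return out


def build_network(segments: Iterable, snap_tol_m: float = 1.0) -> RoadNetwork:
    """Planarize polyline segments into a routable graph.

    Segments are split at every mutual crossing (GEOS noding), endpoints
    within ``snap_tol_m`` of each other are merged into a single node, and
    edge lengths are recomputed from the corrected geometry.  Zero-length
    pieces surviving after snapping are dropped with a warning.
    """
    lines = [l for l in _as_linestrings(segments) if not l.is_empty]
    if not lines:
        raise ValueError("no road segments supplied")
    if not all(np.isfinite(np.asarray(l.coords)).all() for l in lines):
        raise ValueError("road segment with non-finite coordinates")

    # unary_union both nodes the arrangement and dissolves duplicate pieces
    noded = unary_union(lines)
    pieces = sorted(
        (g for g in shapely.get_parts(noded) if isinstance(g, LineString)),
        key=lambda g: g.wkb,
    )

    # cluster piece endpoints within snap_tol_m (union-find over KD-tree pairs)
    endpoints = np.array(
        [c for g in pieces for c in (g.coords[0], g.coords[-1])], dtype=float
    )
    tree = cKDTree(endpoints)
    parent = np.arange(len(endpoints))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(snap_tol_m):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(i) for i in range(len(endpoints))])
    # node position = lexicographically smallest endpoint of the cluster
    cluster_pos: dict[int, tuple[float, float]] = {}
    for i, r in enumerate(roots):
        p = (endpoints[i, 0], endpoints[i, 1])
        if r not in cluster_pos or p < cluster_pos[r]:
            cluster_pos[r] = p
    node_of_root = {
        r: nid
        for nid, r in enumerate(sorted(cluster_pos, key=cluster_pos.get))
    }

    graph = nx.MultiGraph()
    for r, nid in node_of_root.items():
        x, y = cluster_pos[r]
        graph.add_node(nid, x=x, y=y)

    edge_index: list[tuple[int, int, int]] = []
    n_dropped = 0
    for k_piece, geom in enumerate(pieces):
        u = node_of_root[roots[2 * k_piece]]
        v = node_of_root[roots[2 * k_piece + 1]]
        coords = list(geom.coords)
        coords[0] = cluster_pos[roots[2 * k_piece]]
        coords[-1] = cluster_pos[roots[2 * k_piece + 1]]
        snapped = LineString(coords)
        if u == v and snapped.length <= snap_tol_m:
            n_dropped += 1
            continue
        edge_id = len(edge_index)
        key = graph.add_edge(
            u, v, geometry=snapped, length_m=snapped.length, edge_id=edge_id
        )
        edge_index.append((u, v, key))
    if n_dropped:
        logger.warning("dropped %d zero-length segment(s) after snapping", n_dropped)
    if not edge_index:
        raise ValueError("all segments collapsed to zero length after snapping")

    graph.remove_nodes_from(list(nx.isolates(graph)))
    return RoadNetwork(graph=graph, edge_index=edge_index)


def snap_point(
    network: RoadNetwork, point, max_snap_m: float = 5000.0
) -> NetworkLocation:
    """Attach a point to the nearest point on the nearest edge.

    Deterministic tie-break: among equidistant edges the lowest ``edge_id``
    wins.  Raises :class:`SnapError` if the nearest edge is farther than
    ``max_snap_m``.
    """
    pt = Point(point) if not isinstance(point, Point) else point
    geoms = np.array(network.edge_geometries(), dtype=object)
    dists = shapely.distance(geoms, pt)
    best = int(np.argmin(dists))  # argmin takes the first (= lowest id) on ties
    if dists[best] > max_snap_m:
        raise SnapError(
            f"point {pt.wkt} is {dists[best]:.1f} m from the nearest road "
            f"(max_snap_m={max_snap_m})"
        )
    geom = geoms[best]
    offset = float(np.clip(geom.project(pt), 0.0, geom.length))
    return NetworkLocation(best, offset, float(dists[best]))


@dataclass
class ServiceArea:
    """Reached subnetwork within a distance cutoff of a facility set.

    ``intervals[edge_id]`` lists merged ``(start_m, end_m)`` arc-length
    spans of the edge that lie within the cutoff; ``source_points`` are the
    snapped origin points (the entire reached geometry when cutoff is 0).
    """

    cutoff_m: float
    source_ids: tuple[str, ...]
    intervals: dict[int, list[tuple[float, float]]]
    source_points: list[Point]
    network: RoadNetwork = field(repr=False)
    level: str | None = None

    @property
    def geometry(self):
        """Union of reached partial/full edge polylines and source points."""
        parts: list = list(self.source_points)
        for eid, ivs in self.intervals.items():
            geom = self.network.edge_data(eid)["geometry"]
            for a, b in ivs:
                if b - a > 1e-9:
                    parts.append(substring(geom, a, b))
                else:
                    parts.append(geom.interpolate(0.5 * (a + b)))
        if not parts:
            return MultiLineString([])
        return unary_union(parts)

    def buffered(self, buffer_m: float):
        return buffer_service_area(self, buffer_m)


def _seeded_dijkstra(
    graph: nx.MultiGraph, seeds: dict[int, float]
) -> dict[int, float]:
    """Shortest distances to all nodes given per-node starting distances."""
    dist: dict[int, float] = {}
    pq = [(d, n) for n, d in seeds.items()]
    heapq.heapify(pq)
    while pq:
        d, n = heapq.heappop(pq)
        if n in dist:
            continue
        dist[n] = d
        for nbr, keyed in graph.adj[n].items():
            if nbr in dist:
                continue
            w = min(attrs["length_m"] for attrs in keyed.values())
            heapq.heappush(pq, (d + w, nbr))
    return dist


def _merge_intervals(
    ivs: list[tuple[float, float]], eps: float = 1e-9
) -> list[tuple[float, float]]:
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1] + eps:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def service_area(
    network: RoadNetwork,
    sources: Sequence[NetworkLocation],
    cutoff_m: float,
    source_ids: Sequence[str] = (),
    level: str | None = None,
) -> ServiceArea:
    """All road geometry within network distance ``cutoff_m`` of any source.

    Multi-source shortest paths run over edge lengths; an interior point of
    an edge is reached if it lies within the cutoff travelling from either
    endpoint, or directly along the edge from a source snapped to that edge.
    Unreachable components are simply excluded.
    """
    if cutoff_m < 0:
        raise ValueError("cutoff_m must be nonnegative")
    if not sources:
        raise ValueError("no source locations supplied")

    seeds: dict[int, float] = {}
    per_edge_sources: dict[int, list[float]] = {}
    source_points = []
    for src in sources:
        u, v, _ = network.edge_index[src.edge_id]
        length = network.edge_data(src.edge_id)["length_m"]
        seeds[u] = min(seeds.get(u, np.inf), src.offset_m)
        seeds[v] = min(seeds.get(v, np.inf), length - src.offset_m)
        per_edge_sources.setdefault(src.edge_id, []).append(src.offset_m)
        source_points.append(network.locate(src))

    dist = _seeded_dijkstra(network.graph, seeds)

    intervals: dict[int, list[tuple[float, float]]] = {}
    for eid, (u, v, k) in enumerate(network.edge_index):
        length = network.graph.edges[u, v, k]["length_m"]
        ivs: list[tuple[float, float]] = []
        du = dist.get(u, np.inf)
        dv = dist.get(v, np.inf)
        if du <= cutoff_m:
            ivs.append((0.0, min(length, cutoff_m - du)))
        if dv <= cutoff_m:
            ivs.append((max(0.0, length - (cutoff_m - dv)), length))
        for off in per_edge_sources.get(eid, ()):
            ivs.append(
                (max(0.0, off - cutoff_m), min(length, off + cutoff_m))
            )
        if ivs:
            intervals[eid] = _merge_intervals(ivs)

    return ServiceArea(
        cutoff_m=cutoff_m,
        source_ids=tuple(source_ids),
        intervals=intervals,
        source_points=source_points,
        network=network,
        level=level,
    )


def buffer_service_area(sa: ServiceArea, buffer_m: float):
    """Planar buffer (round caps and joins) of the reached geometry.

    An empty service area yields an empty polygon.
    """
    if buffer_m <= 0:
        raise ValueError("buffer_m must be positive")
    geom = sa.geometry
    if geom.is_empty:
        return shapely.Polygon()
    poly = geom.buffer(buffer_m, cap_style="round", join_style="round")
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    return poly


def network_distances_to_samples(
    network: RoadNetwork,
    sources: Sequence[NetworkLocation],
    step_m: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample every edge at ``step_m`` and return each sample's network
    distance to the nearest source.

    Returns ``(edge_ids, offsets, distances)`` arrays.  Distance at offset
    ``t`` on edge ``(u, v)`` is the best of: via ``u``, via ``v``, or
    directly along the edge from a source snapped to it.  Useful for
    diagnostics and cross-checks of :func:`service_area`.
    """
    seeds: dict[int, float] = {}
    per_edge_sources: dict[int, list[float]] = {}
    for src in sources:
        u, v, _ = network.edge_index[src.edge_id]
        length = network.edge_data(src.edge_id)["length_m"]
        seeds[u] = min(seeds.get(u, np.inf), src.offset_m)
        seeds[v] = min(seeds.get(v, np.inf), length - src.offset_m)
        per_edge_sources.setdefault(src.edge_id, []).append(src.offset_m)
    dist = _seeded_dijkstra(network.graph, seeds)

    eids, offs, ds = [], [], []
    for eid, (u, v, k) in enumerate(network.edge_index):
        length = network.graph.edges[u, v, k]["length_m"]
        t = np.arange(0.0, length + step_m / 2, step_m)
        t[-1] = min(t[-1], length)
        d = np.minimum(dist.get(u, np.inf) + t, dist.get(v, np.inf) + (length - t))
        for off in per_edge_sources.get(eid, ()):
            d = np.minimum(d, np.abs(t - off))
        eids.append(np.full(t.shape, eid))
        offs.append(t)
        ds.append(d)
    return np.concatenate(eids), np.concatenate(offs), np.concatenate(ds)
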