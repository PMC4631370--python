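"""Independent oracles for cross-checking the implementation.

Everything here is deliberately written from first principles — brute-force
enumeration, O(n²) geometry, per-cell Python loops, and a 1-m lattice graph
routed with networkx's own Dijkstra — and must stay decoupled from the code
paths it checks.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from shapely.geometry import Point


# ---------------------------------------------------------------------------
# facility classification
# ---------------------------------------------------------------------------

_ORACLE_A = ["overnight_beds", "duty_24h", "water", "electricity",
             "telephone_functioning", "latrines_onsite"]
_ORACLE_B_EXTRA = ["iv_fluids", "blood_products", "has_forceps",
                   "has_needle_driver", "has_sterile_scissors",
                   "local_anesthesia", "sterile_dressings",
                   "supplemental_oxygen"]


def classify_oracle(attrs: dict) -> dict:
    """Score-counting re-statement of the capability criteria.

    ``attrs`` maps attribute name -> bool/int (no missing values).
    Returns dict with keys a, b, c, x.
    """
    a_score = sum(1 for k in _ORACLE_A if attrs[k])
    if attrs["n_qualified_providers"] >= 2:
        a_score += 1
    a = a_score == len(_ORACLE_A) + 1

    b_score = sum(1 for k in _ORACLE_B_EXTRA if attrs[k])
    b = a and b_score == len(_ORACLE_B_EXTRA)

    c_by_designation = bool(attrs["tertiary_designation"])
    c_by_criteria = (
        b and attrs["n_inpatient_beds"] >= 51 and attrs["surgeon_on_staff"]
    )
    c = c_by_designation or c_by_criteria
    return {"a": a, "b": b, "c": c, "x": not (a or b or c)}


def random_attr_vector(rng: np.random.Generator) -> dict:
    """A random point of the attribute space, biased so every criterion is
    exercised both ways with useful frequency."""
    attrs = {}
    p = rng.uniform(0.3, 0.9)
    for k in _ORACLE_A + _ORACLE_B_EXTRA + ["tertiary_designation",
                                            "surgeon_on_staff"]:
        attrs[k] = bool(rng.random() < p)
    attrs["tertiary_designation"] = bool(rng.random() < 0.1)
    attrs["n_qualified_providers"] = int(rng.integers(0, 6))
    attrs["n_inpatient_beds"] = int(rng.choice([0, 10, 49, 50, 51, 60, 200]))
    return attrs


# ---------------------------------------------------------------------------
# planarization: O(n²) pairwise segment-intersection splitter
# ---------------------------------------------------------------------------

def _seg_intersection(p1, p2, p3, p4, eps=1e-12):
    """Parametric proper/touching intersection of two straight segments;
    returns (t, u) in [0,1]² or None.  Collinear overlaps return None."""
    d1 = p2 - p1
    d2 = p4 - p3
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < eps:
        return None
    r = p3 - p1
    t = (r[0] * d2[1] - r[1] * d2[0]) / denom
    u = (r[0] * d1[1] - r[1] * d1[0]) / denom
    if -eps <= t <= 1 + eps and -eps <= u <= 1 + eps:
        return min(max(t, 0.0), 1.0), min(max(u, 0.0), 1.0)
    return None


def brute_planarize(segments, round_decimals: int = 6):
    """Split 2-point segments at all mutual intersections.

    Returns ``(n_nodes, n_edges)`` of the resulting arrangement.  Intended
    for segments in general position (no collinear overlaps).
    """
    segs = [(np.asarray(a, float), np.asarray(b, float)) for a, b in segments]
    cut_ts: list[list[float]] = [[0.0, 1.0] for _ in segs]
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            hit = _seg_intersection(*segs[i], *segs[j])
            if hit is not None:
                cut_ts[i].append(hit[0])
                cut_ts[j].append(hit[1])

    nodes = set()
    n_edges = 0
    for (a, b), ts in zip(segs, cut_ts):
        ts = sorted(set(ts))
        pts = [tuple(np.round(a + t * (b - a), round_decimals)) for t in ts]
        for q1, q2 in zip(pts[:-1], pts[1:]):
            if q1 != q2:
                n_edges += 1
                nodes.add(q1)
                nodes.add(q2)
    return len(nodes), n_edges


# ---------------------------------------------------------------------------
# nearest point on a set of polylines (pure numpy)
# ---------------------------------------------------------------------------

def brute_nearest(edge_coord_lists, point):
    """Exhaustive nearest-point search over polylines.

    Returns ``(edge_index, offset_m, distance)`` with ties broken by lowest
    edge index (then smallest offset).
    """
    px, py = float(point[0]), float(point[1])
    best = None
    for ei, coords in enumerate(edge_coord_lists):
        coords = np.asarray(coords, float)
        cum = 0.0
        for k in range(len(coords) - 1):
            a, b = coords[k], coords[k + 1]
            d = b - a
            L2 = float(d @ d)
            t = 0.0 if L2 == 0 else min(1.0, max(0.0, ((px - a[0]) * d[0] + (py - a[1]) * d[1]) / L2))
            proj = a + t * d
            dist = math.hypot(px - proj[0], py - proj[1])
            off = cum + t * math.sqrt(L2)
            cand = (dist, ei, off)
            if best is None or (cand[0] < best[0] - 1e-12) or (
                abs(cand[0] - best[0]) <= 1e-12 and (ei, off) < (best[1], best[2])
            ):
                best = cand
            cum += math.sqrt(L2)
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# dense-sampling lattice Dijkstra over the road graph
# ---------------------------------------------------------------------------

def lattice_distances(network, sources, step_m: float = 1.0):
    """Exact network distances at ≤ ``step_m``-spaced samples of every edge.

    Every edge is subdivided into a chain of lattice nodes; a virtual source
    node attaches to the lattice nodes adjacent to each source with the
    exact residual offsets, and networkx's Dijkstra does the routing.  At
    the sample points the distances are exact (not approximations), because
    shortest paths only ever traverse whole edges plus a terminal
    along-edge stretch that the chain represents at full resolution.

    Returns a list of per-edge dicts: ``{"edge_id", "ts", "dists", "xs",
    "ys"}`` where ``ts`` are arc-length offsets of the samples.
    """
    G = nx.Graph()
    per_edge = []
    chain_nodes: dict[int, list] = {}
    chain_ts: dict[int, np.ndarray] = {}

    def add_min_edge(n1, n2, w):
        if G.has_edge(n1, n2):
            G[n1][n2]["weight"] = min(G[n1][n2]["weight"], w)
        else:
            G.add_edge(n1, n2, weight=w)

    for eid, (u, v, _k) in enumerate(network.edge_index):
        geom = network.edge_data(eid)["geometry"]
        L = geom.length
        n = max(1, int(math.ceil(L / step_m)))
        ts = np.linspace(0.0, L, n + 1)
        nodes = (
            [("n", u)]
            + [("e", eid, i) for i in range(1, n)]
            + [("n", v)]
        )
        for n1, n2 in zip(nodes[:-1], nodes[1:]):
            add_min_edge(n1, n2, L / n)
        chain_nodes[eid] = nodes
        chain_ts[eid] = ts
        pts = [geom.interpolate(t) for t in ts]
        per_edge.append(
            {
                "edge_id": eid,
                "ts": ts,
                "xs": np.array([p.x for p in pts]),
                "ys": np.array([p.y for p in pts]),
            }
        )

    SRC = ("virtual-source",)
    G.add_node(SRC)
    for src in sources:
        ts = chain_ts[src.edge_id]
        nodes = chain_nodes[src.edge_id]
        i = int(np.searchsorted(ts, src.offset_m, side="right")) - 1
        i = min(max(i, 0), len(ts) - 2)
        add_min_edge(SRC, nodes[i], src.offset_m - ts[i])
        add_min_edge(SRC, nodes[i + 1], ts[i + 1] - src.offset_m)

    dist = nx.single_source_dijkstra_path_length(G, SRC, weight="weight")
    for eid, entry in enumerate(per_edge):
        nodes = chain_nodes[eid]
        entry["dists"] = np.array([dist.get(nd, np.inf) for nd in nodes])
    return per_edge


def in_intervals(t: float, intervals, eps: float = 1e-9) -> bool:
    return any(a - eps <= t <= b + eps for a, b in intervals)


# ---------------------------------------------------------------------------
# per-cell zonal oracles (plain Python loops)
# ---------------------------------------------------------------------------

def cell_population_oracle(raster, polygon) -> float:
    """Sum population cell-by-cell with an explicit covers() check."""
    cs = raster.cell_size_m
    total = 0.0
    for row in range(raster.n_rows):
        for col in range(raster.n_cols):
            v = raster.values[row, col]
            if v == raster.nodata:
                continue
            cx = raster.x_origin + cs * (col + 0.5)
            cy = raster.y_origin + cs * (raster.n_rows - row - 0.5)
            if polygon.covers(Point(cx, cy)):
                total += v
    return total


def cell_covered_proportion_oracle(raster, coverage_polygon, region) -> float | None:
    cs = raster.cell_size_m
    num = denom = 0.0
    for row in range(raster.n_rows):
        for col in range(raster.n_cols):
            v = raster.values[row, col]
            if v == raster.nodata:
                continue
            cx = raster.x_origin + cs * (col + 0.5)
            cy = raster.y_origin + cs * (raster.n_rows - row - 0.5)
            pt = Point(cx, cy)
            if region.covers(pt):
                denom += v
                if coverage_polygon.covers(pt):
                    num += v
    if denom <= 0:
        return None
    return num / denom
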