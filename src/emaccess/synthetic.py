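"""Synthetic countries for end-to-end pipeline testing.

Real inputs for this kind of analysis — facility audits with geocodes, a
national digitized road network, a WorldPop-style population raster and
administrative boundaries — are access-restricted or heavily versioned.
The generator emulates their statistical structure instead:

* settlements with log-normal populations, placed with minimum separation;
* population allocated to raster cells with Gaussian density decay around
  settlement centers (an urban core plus a wider rural halo), conserving
  each settlement's drawn population exactly;
* a road network of trunk roads (minimum spanning tree over settlements,
  with a few extra links creating cycles) and radial branch roads, which the
  pipeline then planarizes;
* facilities sited at settlements (population-weighted), a configurable
  fraction scattered along rural roads, with audit-attribute vectors drawn
  hierarchically — target capability level first, then attributes consistent
  with it — so realized Level A/B/C prevalence matches the configured rates;
* administrative regions as a Voronoi partition seeded by the largest
  settlements.

Two presets bracket the density contrast of interest: ``sparse`` (a large,
thinly peopled country, ~3 persons/km²) and ``dense`` (small and crowded,
~360 persons/km²), with equal facility counts so coverage differences
reflect geography, not supply.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import distance_matrix
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .facilities import BOOL_ATTRS, FacilityRecord, roster_to_frame
from .io import feature, write_geojson
from .roadnet import RoadNetwork, build_network
from .zonal import AdminRegion, PopulationRaster

__all__ = [
    "CountrySpec",
    "Country",
    "generate_country",
    "make_disconnected_variant",
    "sparse_spec",
    "dense_spec",
]

_A_BOOLS = (
    "overnight_beds", "duty_24h", "water", "electricity",
    "telephone_functioning", "latrines_onsite",
)
_B_BOOLS = (
    "iv_fluids", "blood_products", "has_forceps", "has_needle_driver",
    "has_sterile_scissors", "local_anesthesia", "sterile_dressings",
    "supplemental_oxygen",
)


@dataclass(frozen=True)
class CountrySpec:
    """Parameters of a synthetic country; the seed fixes every draw."""

    seed: int = 0
    extent_m: float = 100_000.0
    n_settlements: int = 12
    settlement_pop_median: float = 8_000.0
    settlement_pop_sigma: float = 1.0
    rural_fraction: float = 0.35
    urban_sigma_m: float = 1_500.0
    rural_sigma_m: float = 12_000.0
    n_branches: int = 3
    branch_len_m: tuple[float, float] = (2_000.0, 8_000.0)
    extra_link_fraction: float = 0.3
    n_facilities: int = 30
    p_a: float = 0.12
    p_b: float = 0.07
    p_c: float = 0.012
    p_designation_only_c: float = 0.0
    rural_facility_fraction: float = 0.1
    one_facility_per_settlement: bool = False
    n_regions: int = 4
    cell_size_m: float = 100.0
    name: str = "synthetic"

    def __post_init__(self):
        if not (0 <= self.p_c <= self.p_b <= self.p_a <= 1):
            raise ValueError("capability prevalences must satisfy 0 ≤ p_C ≤ p_B ≤ p_A ≤ 1")
        if self.n_regions > self.n_settlements:
            raise ValueError("n_regions cannot exceed n_settlements")
        if self.one_facility_per_settlement and self.n_facilities > self.n_settlements:
            raise ValueError(
                "infeasible spec: n_facilities exceeds n_settlements with "
                "one-per-settlement placement"
            )
        if self.extent_m <= 0 or self.cell_size_m <= 0:
            raise ValueError("extent_m and cell_size_m must be positive")


@dataclass
class Country:
    """A generated country bundle in the formats the pipeline consumes."""

    spec: CountrySpec
    settlements: pd.DataFrame  # x, y, population
    roads: list[LineString]
    regions: list[AdminRegion]
    raster: PopulationRaster
    facilities: list[FacilityRecord]
    network: RoadNetwork = field(repr=False, default=None)

    def write(self, out_dir) -> dict[str, Path]:
        """Emit roads.geojson, regions.geojson, population.asc,
        facilities.csv into ``out_dir``; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "roads": out / "roads.geojson",
            "regions": out / "regions.geojson",
            "raster": out / "population.asc",
            "facilities": out / "facilities.csv",
        }
        write_geojson(
            paths["roads"],
            (feature(g, road_id=i) for i, g in enumerate(self.roads)),
        )
        write_geojson(
            paths["regions"],
            (
                feature(r.geometry, region_id=r.region_id, name=r.name,
                        admin_level=r.admin_level)
                for r in self.regions
            ),
        )
        self.raster.write_ascii(paths["raster"])
        roster_to_frame(self.facilities).to_csv(paths["facilities"], index=False)
        return paths


def _place_settlements(rng, spec: CountrySpec) -> np.ndarray:
    margin = 0.08 * spec.extent_m
    min_sep = 0.7 * (spec.extent_m - 2 * margin) / math.sqrt(spec.n_settlements)
    pts: list[np.ndarray] = []
    for _ in range(20_000):
        cand = rng.uniform(margin, spec.extent_m - margin, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == spec.n_settlements:
                return np.array(pts)
    raise ValueError("could not place settlements with the required separation")


def _trunk_and_branches(rng, spec: CountrySpec, centers: np.ndarray) -> list[LineString]:
    n = len(centers)
    roads: list[LineString] = []

    def bent_line(a, b):
        # one perpendicular-jittered midpoint makes trunks gently non-straight
        mid = 0.5 * (a + b)
        d = b - a
        norm = np.hypot(*d)
        perp = np.array([-d[1], d[0]]) / max(norm, 1e-9)
        mid = mid + perp * rng.normal(0.0, 0.04 * norm)
        return LineString([tuple(a), tuple(mid), tuple(b)])

    if n > 1:
        dm = distance_matrix(centers, centers)
        mst = minimum_spanning_tree(dm).tocoo()
        linked = set()
        for i, j in zip(mst.row, mst.col):
            roads.append(bent_line(centers[i], centers[j]))
            linked.add(frozenset((int(i), int(j))))
        # extra nearest-neighbour links create cycles
        order = np.argsort(dm, axis=1)
        for i in range(n):
            for j in order[i, 1:3]:
                pair = frozenset((int(i), int(j)))
                if pair not in linked and rng.random() < spec.extra_link_fraction:
                    roads.append(bent_line(centers[i], centers[int(j)]))
                    linked.add(pair)

    lo, hi = spec.branch_len_m
    for i in range(n):
        for _ in range(spec.n_branches):
            ang = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(lo, hi)
            end = centers[i] + length * np.array([math.cos(ang), math.sin(ang)])
            end = np.clip(end, 0.0, spec.extent_m)
            if np.hypot(*(end - centers[i])) > 1.0:
                roads.append(LineString([tuple(centers[i]), tuple(end)]))
    return roads


def _allocate_population(
    rng, spec: CountrySpec, centers: np.ndarray, pops: np.ndarray
) -> PopulationRaster:
    n_cells = int(math.ceil(spec.extent_m / spec.cell_size_m))
    cs = spec.cell_size_m
    xs = cs * (np.arange(n_cells) + 0.5)
    ys = cs * (n_cells - np.arange(n_cells) - 0.5)  # row 0 on top
    X, Y = np.meshgrid(xs, ys)
    values = np.zeros((n_cells, n_cells), dtype=float)

    for (cx, cy), pop in zip(centers, pops):
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        urban = int(round(pop * (1.0 - spec.rural_fraction)))
        rural = int(pop) - urban
        for count, sigma in ((urban, spec.urban_sigma_m), (rural, spec.rural_sigma_m)):
            if count <= 0:
                continue
            w = np.exp(-d2 / (2.0 * sigma * sigma)).ravel()
            w[w < 1e-12] = 0.0
            values += rng.multinomial(count, w / w.sum()).reshape(values.shape)

    return PopulationRaster(
        values=values, x_origin=0.0, y_origin=0.0, cell_size_m=cs, nodata=-9999.0
    )


def _voronoi_regions(spec: CountrySpec, centers: np.ndarray, pops: np.ndarray) -> list[AdminRegion]:
    # seed the partition with the n_regions most populous settlements
    order = np.lexsort((np.arange(len(pops)), -pops))[: spec.n_regions]
    seeds = centers[np.sort(order)]
    extent = box(0.0, 0.0, spec.extent_m, spec.extent_m)
    if len(seeds) == 1:
        cells = [extent]
    else:
        # generous envelope so the clipped cells tile the extent completely
        diagram = voronoi_diagram(
            MultiPoint([tuple(p) for p in seeds]),
            envelope=box(-spec.extent_m, -spec.extent_m,
                         2 * spec.extent_m, 2 * spec.extent_m),
        )
        cells = []
        for p in seeds:
            cell = next(
                g for g in diagram.geoms if g.intersects(Point(tuple(p)))
            )
            cells.append(cell.intersection(extent))
    return [
        AdminRegion(region_id=f"R{i + 1:02d}", name=f"Region {i + 1:02d}",
                    geometry=cell, admin_level=1)
        for i, cell in enumerate(cells)
    ]


def _draw_attributes(rng, category: str) -> dict:
    """Audit attributes consistent with a target capability category.

    Categories: ``X`` (no capability), ``A``, ``B``, ``C`` (criteria route)
    and ``CD`` (designation-only tertiary — carries the tertiary flag but
    fails basic infrastructure, so it gains no A/B flag).
    """
    attrs = {a: bool(rng.random() < 0.35) for a in BOOL_ATTRS}
    attrs["n_qualified_providers"] = int(rng.poisson(1.2))
    attrs["n_inpatient_beds"] = int(rng.poisson(8))
    attrs["tertiary_designation"] = False

    def satisfy_a():
        for a in _A_BOOLS:
            attrs[a] = True
        attrs["n_qualified_providers"] = 2 + int(rng.poisson(2))

    def satisfy_b():
        satisfy_a()
        for a in _B_BOOLS:
            attrs[a] = True

    if category == "A":
        satisfy_a()
        for a in _B_BOOLS:
            attrs[a] = bool(rng.random() < 0.4)
        attrs[_B_BOOLS[rng.integers(len(_B_BOOLS))]] = False
    elif category == "B":
        satisfy_b()
        beds = int(rng.integers(10, 81))
        attrs["n_inpatient_beds"] = beds
        attrs["surgeon_on_staff"] = bool(rng.random() < 0.5) if beds <= 50 else False
    elif category == "C":
        satisfy_b()
        attrs["n_inpatient_beds"] = int(rng.integers(51, 401))
        attrs["surgeon_on_staff"] = True
        attrs["tertiary_designation"] = bool(rng.random() < 0.5)
    elif category == "CD":
        attrs["tertiary_designation"] = True
        attrs["water"] = False
        attrs["blood_products"] = False
    elif category == "X":
        fail = rng.integers(len(_A_BOOLS) + 1)
        if fail < len(_A_BOOLS):
            attrs[_A_BOOLS[fail]] = False
        else:
            attrs["n_qualified_providers"] = int(rng.integers(0, 2))
    else:  # pragma: no cover
        raise ValueError(category)
    return attrs


def _draw_facilities(
    rng, spec: CountrySpec, centers: np.ndarray, pops: np.ndarray,
    roads: list[LineString],
) -> list[FacilityRecord]:
    p = pops / pops.sum()
    if spec.one_facility_per_settlement:
        sites = rng.choice(len(centers), size=spec.n_facilities, replace=False, p=p)
    else:
        sites = rng.choice(len(centers), size=spec.n_facilities, p=p)

    records = []
    for i, site in enumerate(sites):
        if rng.random() < spec.rural_facility_fraction and roads:
            road = roads[int(rng.integers(len(roads)))]
            pos = road.interpolate(rng.uniform(0, road.length))
            xy = np.array([pos.x, pos.y]) + rng.normal(0, 800.0, size=2)
        else:
            xy = centers[site] + rng.normal(0, 300.0, size=2)
        xy = np.clip(xy, 0.0, spec.extent_m)

        u = rng.random()
        if u < spec.p_c:
            category = "C"
        elif u < spec.p_b:
            category = "B"
        elif u < spec.p_a:
            category = "A"
        elif u < spec.p_a + spec.p_designation_only_c:
            category = "CD"
        else:
            category = "X"
        records.append(
            FacilityRecord(
                facility_id=f"F{i + 1:04d}",
                name=f"Facility {i + 1:04d}",
                x=float(xy[0]),
                y=float(xy[1]),
                **_draw_attributes(rng, category),
            )
        )
    return records


def generate_country(spec: CountrySpec) -> Country:
    """Generate a full synthetic country from a :class:`CountrySpec`.

    The raster's total population equals the sum of the drawn settlement
    populations exactly (multinomial allocation conserves counts).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_settlements(rng, spec)
    pops = np.maximum(
        20,
        np.round(
            rng.lognormal(
                math.log(spec.settlement_pop_median),
                spec.settlement_pop_sigma,
                size=spec.n_settlements,
            )
        ).astype(int),
    )
    roads = _trunk_and_branches(rng, spec, centers)
    raster = _allocate_population(rng, spec, centers, pops)
    regions = _voronoi_regions(spec, centers, pops)
    facilities = _draw_facilities(rng, spec, centers, pops, roads)
    settlements = pd.DataFrame(
        {"x": centers[:, 0], "y": centers[:, 1], "population": pops}
    )
    return Country(
        spec=spec,
        settlements=settlements,
        roads=roads,
        regions=regions,
        raster=raster,
        facilities=facilities,
    )


def make_disconnected_variant(
    country: Country, n_cut_edges: int = 1, seed: int = 0
) -> Country:
    """Sever bridge roads so the network splits into ≥ 2 components.

    Populations on a component without capable facilities then drop out of
    network coverage while possibly remaining inside Euclidean coverage —
    the stress case for unreachable rural populations.  The returned
    country's roads are the planarized edges of the original network minus
    the cut edges.
    """
    network = build_network(country.roads)
    rng = np.random.default_rng(seed)
    graph = network.graph.copy()
    n_before = nx.number_connected_components(graph)

    removed: list[int] = []
    for _ in range(n_cut_edges):
        simple = nx.Graph(graph)
        bridge_pairs = {frozenset(b) for b in nx.bridges(simple)}
        candidates = [
            eid
            for eid, (u, v, k) in enumerate(network.edge_index)
            if eid not in removed
            and frozenset((u, v)) in bridge_pairs
            and graph.number_of_edges(u, v) == 1
            and graph.has_edge(u, v)
        ]
        if not candidates:
            raise ValueError("network has no removable bridge left to cut")
        eid = candidates[int(rng.integers(len(candidates)))]
        u, v, k = network.edge_index[eid]
        graph.remove_edge(u, v, k)
        removed.append(eid)

    if nx.number_connected_components(graph) <= n_before:
        raise ValueError("cutting the chosen edges did not disconnect the network")

    new_roads = [
        network.edge_data(eid)["geometry"]
        for eid in range(network.n_edges)
        if eid not in removed
    ]
    return replace(country, roads=new_roads, network=None)


def sparse_spec(seed: int = 0) -> CountrySpec:
    """A large, thinly settled country (~3 persons/km²): few settlements,
    long distances, coarse 500 m cells over a 120 km square."""
    return CountrySpec(
        seed=seed,
        extent_m=120_000.0,
        n_settlements=10,
        settlement_pop_median=2_500.0,
        settlement_pop_sigma=1.0,
        rural_fraction=0.5,
        urban_sigma_m=1_200.0,
        rural_sigma_m=18_000.0,
        n_facilities=30,
        n_regions=5,
        cell_size_m=500.0,
        name="sparse",
    )


def dense_spec(seed: int = 0) -> CountrySpec:
    """A small, crowded country (~360 persons/km²): many large settlements
    close together, 250 m cells over a 50 km square."""
    return CountrySpec(
        seed=seed,
        extent_m=50_000.0,
        n_settlements=12,
        settlement_pop_median=60_000.0,
        settlement_pop_sigma=0.8,
        rural_fraction=0.3,
        urban_sigma_m=2_000.0,
        rural_sigma_m=8_000.0,
        n_facilities=30,
        n_regions=4,
        cell_size_m=250.0,
        name="dense",
    )
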