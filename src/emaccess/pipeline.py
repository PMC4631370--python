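"""End-to-end coverage pipeline.

Orchestrates classification → per-level service areas → zonal aggregation
into a coverage table: for every capability level (A, B, C) and distance
cutoff (5, 10, 50 km by default), the proportion of the national and of each
region's population living inside the buffered network catchment of the
capable facilities.  A 1,000 m buffer around the reached roads captures
people living near, but not exactly on, mapped roads; shrinking and growing
that buffer by ±50% yields the uncertainty interval (UI) reported alongside
each proportion.

A Euclidean variant replaces network catchments with plain disks around the
facilities — the classical straight-line comparison (no extra road buffer is
applied there).

Scale and units: all geometry in projected planar meters; proportions in
[0, 1] internally, percent only in display tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point
from shapely.ops import unary_union

from . import io as gio
from .facilities import (
    CapabilityProfile,
    FacilityRecord,
    LEVELS,
    classify_roster,
    read_roster_csv,
)
from .roadnet import (
    NetworkLocation,
    RoadNetwork,
    SnapError,
    build_network,
    service_area,
    snap_point,
)
from .zonal import AdminRegion, PopulationRaster, region_assignment, regions_from_geojson

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_coverage",
    "uncertainty_interval",
    "euclidean_coverage",
    "coverage_table",
    "euclidean_table",
    "write_report",
    "percent_display",
]

TABLE_COLUMNS = ["scope", "level", "cutoff_km", "proportion", "ui_low", "ui_high"]


@dataclass
class PipelineConfig:
    """File paths and parameters for one coverage run.

    ``crs`` declares the projected CRS every layer is expected to share; it
    is metadata only — no reprojection is performed, and mismatched
    declarations raise.  ``ui_factor`` is the fractional buffer perturbation
    defining the uncertainty interval.
    """

    facilities: str
    roads: str
    regions: str
    raster: str
    crs: str = "local-meters"
    cutoffs_km: tuple[float, ...] = (5.0, 10.0, 50.0)
    buffer_m: float = 1000.0
    ui_factor: float = 0.5
    max_snap_m: float = 5000.0
    snap_tol_m: float = 1.0
    missing_policy: str = "as_false"
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self):
        self.cutoffs_km = tuple(float(c) for c in self.cutoffs_km)
        if not self.cutoffs_km or any(c <= 0 for c in self.cutoffs_km):
            raise ValueError("cutoffs_km must be positive")
        if list(self.cutoffs_km) != sorted(self.cutoffs_km):
            raise ValueError("cutoffs_km must be ascending")
        if not 0 < self.ui_factor < 1:
            raise ValueError("ui_factor must lie in (0, 1)")
        if self.buffer_m <= 0:
            raise ValueError("buffer_m must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    service_areas: dict = field(default_factory=dict)  # (level, cutoff_m) -> ServiceArea
    profiles: list[CapabilityProfile] = field(default_factory=list)
    summary: pd.DataFrame | None = None
    snap_failures: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _facility_points(records: Sequence[FacilityRecord]) -> dict[str, Point]:
    return {r.facility_id: Point(r.x, r.y) for r in records}


def _coverage_row_block(
    raster: PopulationRaster,
    region_masks: dict[str, np.ndarray],
    covered_masks: Sequence[np.ndarray],
    level: str,
    cutoff_km: float,
) -> list[dict]:
    """National + per-region rows from 1 or 3 covered-cell masks (the middle
    mask is the point estimate; min/max over all give the UI)."""
    valid = raster.valid_mask()
    total = float(raster.values[valid].sum())

    def props(denom_mask):
        denom = float(raster.values[denom_mask].sum())
        if denom <= 0:
            return None
        return [
            float(raster.values[denom_mask & cm].sum()) / denom
            for cm in covered_masks
        ]

    rows = []
    mid = len(covered_masks) // 2

    def make_row(scope, ps):
        if ps is None:
            return {
                "scope": scope, "level": level, "cutoff_km": cutoff_km,
                "proportion": np.nan, "ui_low": np.nan, "ui_high": np.nan,
            }
        return {
            "scope": scope, "level": level, "cutoff_km": cutoff_km,
            "proportion": ps[mid], "ui_low": min(ps), "ui_high": max(ps),
        }

    national = props(valid) if total > 0 else None
    rows.append(make_row("national", national))
    for rid in sorted(region_masks):
        rows.append(make_row(rid, props(region_masks[rid])))
    return rows


def coverage_table(
    records: Sequence[FacilityRecord],
    profiles: Sequence[CapabilityProfile],
    network: RoadNetwork,
    raster: PopulationRaster,
    regions: Sequence[AdminRegion],
    cutoffs_km: Sequence[float] = (5.0, 10.0, 50.0),
    buffer_m: float = 1000.0,
    ui_factor: float | None = 0.5,
    max_snap_m: float = 5000.0,
    levels: Sequence[str] = LEVELS,
) -> PipelineResult:
    """Network-distance coverage per level × cutoff × scope.

    For each level the capable facilities are snapped to the network, one
    union service area per cutoff is built and buffered, and proportions are
    computed raster-wide (national) and per region.  With ``ui_factor`` set,
    the buffer is additionally shrunk/grown by that fraction and the
    min/max of the three proportions become ``ui_low``/``ui_high``.
    Facilities farther than ``max_snap_m`` from any road are excluded and
    reported, as are levels with no capable facility (all-zero rows).
    """
    result = PipelineResult(table=None)
    points = _facility_points(records)
    prof_by_id = {p.facility_id: p for p in profiles}

    locations: dict[str, NetworkLocation] = {}
    for fid, pt in points.items():
        if not any(prof_by_id[fid].has_level(l) for l in levels):
            continue
        try:
            locations[fid] = snap_point(network, pt, max_snap_m)
        except SnapError as exc:
            result.snap_failures.append(fid)
            result.log.append(f"snap failure: {exc}")

    region_masks, outside = region_assignment(raster, regions)
    outside_pop = float(raster.values[outside].sum())
    if outside_pop > 0:
        result.log.append(
            f"population outside all regions: {outside_pop:.0f} persons"
        )

    buffers = [buffer_m]
    if ui_factor is not None:
        buffers = [
            buffer_m * (1 - ui_factor), buffer_m, buffer_m * (1 + ui_factor)
        ]

    rows: list[dict] = []
    for level in levels:
        fids = [
            fid for fid in points
            if prof_by_id[fid].has_level(level) and fid in locations
        ]
        if not fids:
            result.log.append(f"no snapped facility with Level {level} capability")
        for cutoff_km in cutoffs_km:
            cutoff_m = 1000.0 * cutoff_km
            if fids:
                sa = service_area(
                    network,
                    [locations[f] for f in fids],
                    cutoff_m,
                    source_ids=fids,
                    level=level,
                )
                result.service_areas[(level, cutoff_m)] = sa
                covered = [
                    raster.center_mask(sa.buffered(b)) & raster.valid_mask()
                    for b in buffers
                ]
            else:
                covered = [np.zeros(raster.values.shape, dtype=bool)] * len(buffers)
            rows.extend(
                _coverage_row_block(raster, region_masks, covered, level, cutoff_km)
            )

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    # raster-wide national vs population-weighted regional mean consistency
    checks = []
    for (level, cutoff), grp in table.groupby(["level", "cutoff_km"]):
        nat = grp.loc[grp.scope == "national", "proportion"].iloc[0]
        reg = grp[grp.scope != "national"]
        weights = np.array(
            [float(raster.values[region_masks[r]].sum()) for r in reg.scope]
        )
        props = reg.proportion.to_numpy()
        ok = weights.sum() > 0 and np.isfinite(props[weights > 0]).all()
        if ok and math.isfinite(nat) and outside_pop == 0:
            checks.append(abs(nat - float(np.average(props, weights=weights))))
    if checks:
        table.attrs["national_vs_regions_max_diff"] = max(checks)
    result.table = table
    return result


def euclidean_table(
    records: Sequence[FacilityRecord],
    profiles: Sequence[CapabilityProfile],
    raster: PopulationRaster,
    regions: Sequence[AdminRegion],
    radii_km: Sequence[float] = (5.0, 10.0, 50.0),
    levels: Sequence[str] = LEVELS,
) -> PipelineResult:
    """Straight-line variant: union of disks of each radius around capable
    facilities, no road network and no extra buffer.  UI columns collapse to
    the point estimate (no buffer to perturb)."""
    result = PipelineResult(table=None)
    points = _facility_points(records)
    prof_by_id = {p.facility_id: p for p in profiles}
    region_masks, _ = region_assignment(raster, regions)

    rows: list[dict] = []
    for level in levels:
        pts = [points[f] for f in points if prof_by_id[f].has_level(level)]
        for radius_km in radii_km:
            if pts:
                disk = unary_union([p.buffer(1000.0 * radius_km) for p in pts])
                shapely.prepare(disk)
                covered = [raster.center_mask(disk) & raster.valid_mask()]
            else:
                covered = [np.zeros(raster.values.shape, dtype=bool)]
                result.log.append(f"no facility with Level {level} capability")
            rows.extend(
                _coverage_row_block(raster, region_masks, covered, level, radius_km)
            )
    result.table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return result


def _load_inputs(config: PipelineConfig):
    records = read_roster_csv(config.facilities)
    profiles, summary = classify_roster(records, config.missing_policy)
    segments = gio.read_road_segments(config.roads)
    network = build_network(segments, snap_tol_m=config.snap_tol_m)
    raster = PopulationRaster.read_ascii(config.raster)
    regions = regions_from_geojson(gio.read_geojson(config.regions))
    return records, profiles, summary, network, raster, regions


def run_coverage(config: PipelineConfig, with_ui: bool = True) -> PipelineResult:
    """Load all inputs, classify, and compute the network coverage table
    (with uncertainty intervals unless ``with_ui`` is False)."""
    records, profiles, summary, network, raster, regions = _load_inputs(config)
    result = coverage_table(
        records, profiles, network, raster, regions,
        cutoffs_km=config.cutoffs_km,
        buffer_m=config.buffer_m,
        ui_factor=config.ui_factor if with_ui else None,
        max_snap_m=config.max_snap_m,
    )
    result.profiles = profiles
    result.summary = summary
    result.log.insert(0, f"config: {config}")
    return result


def uncertainty_interval(config: PipelineConfig) -> pd.DataFrame:
    """The ``(scope, level, cutoff_km, ui_low, ui_high)`` frame from a full
    run with the buffer perturbed by ``±ui_factor``."""
    table = run_coverage(config, with_ui=True).table
    return table[["scope", "level", "cutoff_km", "ui_low", "ui_high"]].copy()


def euclidean_coverage(
    config: PipelineConfig, radii_km: Sequence[float] | None = None
) -> PipelineResult:
    """Load inputs and compute the Euclidean-disk coverage table."""
    records, profiles, summary, _network, raster, regions = _load_inputs(config)
    result = euclidean_table(
        records, profiles, raster, regions,
        radii_km=radii_km if radii_km is not None else config.cutoffs_km,
    )
    result.profiles = profiles
    result.summary = summary
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def percent_display(p: float | None) -> str:
    """Half-up rounding to one decimal in percent: 0.4875 -> ``"48.8"``;
    undefined proportions display as ``"N/A"``."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "N/A"
    return str(
        (Decimal(repr(float(p))) * 100).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def write_report(
    table: pd.DataFrame, out_dir, prefix: str = "coverage",
    service_areas: dict | None = None, buffer_m: float | None = None,
) -> dict[str, Path]:
    """Write the raw full-precision CSV and the percent display CSV
    (deterministic column order), plus optional service-area GeoJSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    raw = table[TABLE_COLUMNS].copy()
    paths["raw"] = out / f"{prefix}_raw.csv"
    raw.to_csv(paths["raw"], index=False)

    disp = raw.copy()
    for col in ("proportion", "ui_low", "ui_high"):
        disp[col] = [percent_display(v) for v in raw[col]]
    disp = disp.rename(
        columns={"proportion": "percent", "ui_low": "ui_low_percent",
                 "ui_high": "ui_high_percent"}
    )
    paths["display"] = out / f"{prefix}_percent.csv"
    disp.to_csv(paths["display"], index=False)

    if service_areas:
        feats = []
        for (level, cutoff_m), sa in sorted(service_areas.items()):
            props = {"level": level, "cutoff_m": cutoff_m}
            feats.append(gio.feature(sa.geometry, kind="reached", **props))
            if buffer_m:
                feats.append(
                    gio.feature(sa.buffered(buffer_m), kind="buffered",
                                buffer_m=buffer_m, **props)
                )
        paths["service_areas"] = out / f"{prefix}_service_areas.geojson"
        gio.write_geojson(paths["service_areas"], feats)
    return paths


def plot_coverage_map(
    raster: PopulationRaster,
    regions: Sequence[AdminRegion],
    coverage_polygon,
    path,
    title: str = "coverage",
) -> None:
    """Simple coverage map (population shading, region outlines, covered
    area).  Requires matplotlib (the ``plot`` extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    cs = raster.cell_size_m
    extent = [
        raster.x_origin, raster.x_origin + cs * raster.n_cols,
        raster.y_origin, raster.y_origin + cs * raster.n_rows,
    ]
    vals = np.where(raster.valid_mask(), raster.values, np.nan)
    ax.imshow(np.log1p(vals), extent=extent, origin="upper", cmap="Greys")
    for region in regions:
        for poly in getattr(region.geometry, "geoms", [region.geometry]):
            ax.plot(*poly.exterior.xy, color="tab:blue", lw=0.8)
    if coverage_polygon is not None and not coverage_polygon.is_empty:
        for poly in getattr(coverage_polygon, "geoms", [coverage_polygon]):
            ax.fill(*poly.exterior.xy, color="tab:red", alpha=0.3)
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
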