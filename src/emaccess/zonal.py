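"""Gridded-population zonal statistics.

A :class:`PopulationRaster` is a WorldPop-style surface: square cells
(100 m by default) holding estimated resident counts.  Aggregation uses the
*cell-center* rule — a cell belongs to a polygon iff its center point lies
inside or on the boundary (boundary-inclusive).  Cells are small relative to
the 1 km service-area buffer, and the rule lets region partitions conserve
population exactly: :func:`region_population` assigns each cell to exactly
one region (first covering region in sorted id order when a center sits on a
shared boundary).

Raster I/O uses the single-band ESRI ASCII grid format (plain text; nodata
honored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import shape

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationRaster",
    "AdminRegion",
    "population_in",
    "region_assignment",
    "region_population",
    "covered_proportion",
]


@dataclass(frozen=True)
class AdminRegion:
    """One administrative unit: id, display name, polygon, admin level."""

    region_id: str
    name: str
    geometry: shapely.Geometry
    admin_level: int = 1

    def __post_init__(self):
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"region {self.region_id!r}: invalid geometry")


@dataclass
class PopulationRaster:
    """Gridded person counts on a regular square grid.

    ``values`` has shape ``(n_rows, n_cols)`` with row 0 the *top* row (the
    ASCII-grid convention); ``x_origin, y_origin`` is the lower-left corner
    of the grid; ``cell_size_m`` the cell edge.  ``nodata`` cells contribute
    nothing to any sum.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size_m: float = 100.0
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        valid = self.values != self.nodata
        if np.any(self.values[valid] < 0) or not np.all(
            np.isfinite(self.values[valid])
        ):
            raise ValueError("population cells must be finite and nonnegative")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(X, Y)`` of cell-center coordinates, shaped like values."""
        cs = self.cell_size_m
        xs = self.x_origin + cs * (np.arange(self.n_cols) + 0.5)
        # row 0 is the top row
        ys = self.y_origin + cs * (self.n_rows - np.arange(self.n_rows) - 0.5)
        return np.meshgrid(xs, ys)

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    @property
    def total_population(self) -> float:
        return float(self.values[self.valid_mask()].sum())

    def center_mask(self, geometry) -> np.ndarray:
        """Boolean mask of cells whose center lies in/on the geometry."""
        if geometry.is_empty:
            return np.zeros(self.values.shape, dtype=bool)
        X, Y = self.cell_centers()
        shapely.prepare(geometry)
        return shapely.intersects_xy(geometry, X, Y)

    # ---- ESRI ASCII grid I/O ------------------------------------------

    @classmethod
    def read_ascii(cls, path) -> "PopulationRaster":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value",
                ):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            values = np.loadtxt(fh, dtype=float)
        values = np.atleast_2d(values)
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"ASCII grid missing header field {key!r}")
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid data shape does not match header")
        return cls(
            values=values,
            x_origin=header["xllcorner"],
            y_origin=header["yllcorner"],
            cell_size_m=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"ncols {self.n_cols}\nnrows {self.n_rows}\n"
                f"xllcorner {self.x_origin:.6f}\nyllcorner {self.y_origin:.6f}\n"
                f"cellsize {self.cell_size_m:.6f}\n"
                f"NODATA_value {self.nodata:g}\n"
            )
            np.savetxt(fh, self.values, fmt="%.6g")


def population_in(raster: PopulationRaster, polygon) -> float:
    """Sum of population whose cell center lies in/on ``polygon``.

    Nodata cells contribute 0; an empty polygon gives 0.
    """
    if polygon.is_empty:
        return 0.0
    mask = raster.center_mask(polygon) & raster.valid_mask()
    return float(raster.values[mask].sum())


def region_assignment(
    raster: PopulationRaster, regions: Sequence[AdminRegion]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Exclusive cell→region assignment masks by the cell-center rule.

    Each valid cell is assigned to the first region (sorted ``region_id``)
    covering its center; the second return value masks valid cells outside
    every region.  Overlapping regions trigger a warning.
    """
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region_id")
    valid = raster.valid_mask()
    assigned = np.zeros(raster.values.shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    overlap = False
    for region in sorted(regions, key=lambda r: r.region_id):
        mask = raster.center_mask(region.geometry)
        if np.any(mask & assigned):
            overlap = True
        masks[region.region_id] = mask & ~assigned & valid
        assigned |= mask
    if overlap:
        logger.warning("regions overlap: shared cells assigned to lowest region_id")
    return masks, valid & ~assigned


def region_population(
    raster: PopulationRaster, regions: Sequence[AdminRegion]
) -> tuple[dict[str, float], float]:
    """Per-region population by exclusive cell-center assignment.

    Counts over a partition sum exactly to the raster total.  Returns
    ``(counts, remainder)`` with ``remainder`` the population in cells
    outside every region.
    """
    masks, outside = region_assignment(raster, regions)
    counts = {rid: float(raster.values[m].sum()) for rid, m in masks.items()}
    return counts, float(raster.values[outside].sum())


def covered_proportion(
    raster: PopulationRaster, coverage_polygon, region_geometry
) -> float | None:
    """Fraction of a region's population whose cell center also lies in the
    coverage polygon.

    Returns ``None`` (not applicable) when the region holds no population —
    the denominator is undefined.
    """
    valid = raster.valid_mask()
    region_mask = raster.center_mask(region_geometry) & valid
    denom = float(raster.values[region_mask].sum())
    if denom <= 0:
        return None
    num_mask = region_mask & raster.center_mask(coverage_polygon)
    return float(raster.values[num_mask].sum()) / denom


def regions_from_geojson(features) -> list[AdminRegion]:
    """Build :class:`AdminRegion` objects from GeoJSON feature dicts."""
    regions = []
    for feat in features:
        props = feat.get("properties") or {}
        regions.append(
            AdminRegion(
                region_id=str(props["region_id"]),
                name=str(props.get("name", props["region_id"])),
                geometry=shape(feat["geometry"]),
                admin_level=int(props.get("admin_level", 1)),
            )
        )
    return regions
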