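"""Minimal GeoJSON reading and writing (planar coordinates).

Geometries travel as shapely objects; features as ``(geometry, properties)``
pairs.  Coordinates are written verbatim — no CRS transformation happens
here, and a ``crs`` member, when present, is carried as declared metadata
only.
"""

from __future__ import annotations

import json
from typing import Iterable

from shapely.geometry import LineString, MultiLineString, mapping, shape

__all__ = [
    "read_geojson",
    "read_road_segments",
    "write_geojson",
    "feature",
]


def read_geojson(path) -> list[dict]:
    """Return the feature dicts of a GeoJSON FeatureCollection (or wrap a
    bare geometry / single feature)."""
    with open(path) as fh:
        obj = json.load(fh)
    t = obj.get("type")
    if t == "FeatureCollection":
        return obj["features"]
    if t == "Feature":
        return [obj]
    return [{"type": "Feature", "geometry": obj, "properties": {}}]


def read_road_segments(path) -> list[LineString]:
    """Load LineString/MultiLineString features as a flat polyline list."""
    lines: list[LineString] = []
    for feat in read_geojson(path):
        geom = shape(feat["geometry"])
        if isinstance(geom, LineString):
            lines.append(geom)
        elif isinstance(geom, MultiLineString):
            lines.extend(geom.geoms)
        else:
            raise ValueError(
                f"road layer contains non-line geometry {geom.geom_type}"
            )
    return lines


def feature(geometry, **properties) -> dict:
    return {
        "type": "Feature",
        "geometry": mapping(geometry),
        "properties": properties,
    }


def write_geojson(path, features: Iterable[dict], crs: str | None = None) -> None:
    obj: dict = {"type": "FeatureCollection", "features": list(features)}
    if crs:
        obj["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(obj, fh, separators=(",", ":"))
        fh.write("\n")
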