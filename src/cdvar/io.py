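"""Plain-text readers/writers for the pipeline artifacts.

Tabular data round-trips through CSV via pandas; geographic layers
round-trip through GeoJSON (planar km coordinates) with shapely doing the
geometry encoding.  Every writer has a matching reader and the pipeline
relies on the pair being inverse to each other.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape

from .synthetic import Facility, GeographyLayers, RoadSegment

__all__ = [
    "write_roads",
    "read_roads",
    "write_facilities",
    "read_facilities",
    "write_geography",
    "read_geography",
]


def _write_feature_collection(path, geoms, props) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, props)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def write_roads(path, roads: list[RoadSegment]) -> None:
    _write_feature_collection(
        path, [r.geometry for r in roads], [{"aadt": r.aadt} for r in roads]
    )


def read_roads(path) -> list[RoadSegment]:
    data = json.loads(Path(path).read_text())
    roads = []
    for feat in data["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"road feature must be a LineString, got {geom.geom_type}")
        roads.append(RoadSegment(geom, float(feat["properties"]["aadt"])))
    return roads


def write_facilities(path, facilities: list[Facility]) -> None:
    _write_feature_collection(
        path,
        [f.geometry for f in facilities],
        [{"emissions_kg": f.emissions_kg} for f in facilities],
    )


def read_facilities(path) -> list[Facility]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, Point):
            raise ValueError(f"facility feature must be a Point, got {geom.geom_type}")
        out.append(Facility(geom, float(feat["properties"]["emissions_kg"])))
    return out


def write_geography(outdir, geo: GeographyLayers) -> None:
    outdir = Path(outdir)
    write_roads(outdir / "roads.geojson", geo.roads)
    write_facilities(outdir / "facilities.geojson", geo.facilities)
    geo.air_by_tract.to_csv(outdir / "air_by_tract.csv", index=False)


def read_geography(outdir) -> GeographyLayers:
    outdir = Path(outdir)
    return GeographyLayers(
        roads=read_roads(outdir / "roads.geojson"),
        facilities=read_facilities(outdir / "facilities.geojson"),
        air_by_tract=pd.read_csv(outdir / "air_by_tract.csv"),
    )
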