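"""Readers and writers for the pipeline's external formats.

Lakes and accesses travel together in one GeoJSON FeatureCollection
(polygon features keyed by ``lake_id``; point features with ``kind`` and
``lake_id`` properties).  Coordinates are planar meters in a projected
CRS; reprojection happens before data reach this package.  Tables are
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from stonewort.covariates import OccupancyDesign
from stonewort.errors import SchemaError
from stonewort.geo import Access, LakeGeometry, merge_waterbodies


def write_lakes_geojson(lakes: dict[str, LakeGeometry], path: str | Path) -> None:
    features = []
    for lake_id in sorted(lakes):
        lake = lakes[lake_id]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(lake.polygon),
                "properties": {"lake_id": lake_id},
            }
        )
        for a in lake.accesses:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [a.x, a.y]},
                    "properties": {
                        "lake_id": lake_id,
                        "access_id": a.access_id,
                        "kind": a.kind,
                    },
                }
            )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_lakes_geojson(path: str | Path) -> dict[str, LakeGeometry]:
    """Read lakes and accesses; polygons sharing a lake_id are merged."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    polys: dict[str, list] = {}
    accesses: dict[str, list[Access]] = {}
    for feat in payload.get("features", []):
        props = feat.get("properties") or {}
        lake_id = props.get("lake_id")
        if lake_id is None:
            raise SchemaError(f"{path}: feature without lake_id property")
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            polys.setdefault(lake_id, []).append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.setdefault(lake_id, []).extend(geom.geoms)
        elif geom.geom_type == "Point":
            if "access_id" not in props or "kind" not in props:
                raise SchemaError(
                    f"{path}: access point for lake {lake_id!r} needs "
                    "access_id and kind properties"
                )
            accesses.setdefault(lake_id, []).append(
                Access(str(props["access_id"]), geom.x, geom.y, props["kind"])
            )
        else:
            raise SchemaError(f"{path}: unsupported geometry {geom.geom_type}")
    lakes = {}
    for lake_id, parts in sorted(polys.items()):
        lakes[lake_id] = merge_waterbodies(
            lake_id, parts, accesses=accesses.get(lake_id, [])
        )
    return lakes


def read_points_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"point_id", "lake_id", "x", "y"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_visits_csv(path: str | Path) -> pd.DataFrame:
    """Long-format rake table: point_id, lake_id, date, depth_m, taxon, ordinal."""
    df = pd.read_csv(path)
    missing = {"point_id", "lake_id", "date", "depth_m", "taxon", "ordinal"} - set(
        df.columns
    )
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_visits_wide_csv(path: str | Path, taxa: list[str]) -> pd.DataFrame:
    """Wide-format reader: one column per taxon, melted to the long layout."""
    df = pd.read_csv(path)
    missing = {"point_id", "lake_id", "date", "depth_m"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    absent = [t for t in taxa if t not in df.columns]
    if absent:
        raise SchemaError(f"{path}: missing taxon columns {absent}")
    long = df.melt(
        id_vars=["point_id", "lake_id", "date", "depth_m"],
        value_vars=taxa,
        var_name="taxon",
        value_name="ordinal",
    )
    return long.dropna(subset=["ordinal"]).astype({"ordinal": int})


def read_lake_meta_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"lake_id", "first_infested_year"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def export_design(design: OccupancyDesign, directory: str | Path) -> dict[str, Path]:
    """Design matrices as CSV plus a JSON sidecar with the scaling constants."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x_path = directory / "design_X.csv"
    v_path = directory / "design_V.csv"
    side_path = directory / "design_scaling.json"
    X = pd.DataFrame(design.X, columns=design.x_names)
    pd.concat([design.py.reset_index(drop=True), X], axis=1).to_csv(x_path, index=False)
    V = pd.DataFrame(design.V, columns=design.v_names)
    keys = design.visits[["lake_id", "point_id", "year", "k", "date"]].reset_index(
        drop=True
    )
    pd.concat([keys, V.assign(y=design.y)], axis=1).to_csv(v_path, index=False)
    sidecar = {
        "occupancy_columns": design.x_names,
        "detection_columns": design.v_names,
        "scaling": {k: {"mean": m, "sd": s} for k, (m, s) in design.scaling.items()},
        "first_infested": design.first_infested,
    }
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"X": x_path, "V": v_path, "scaling": side_path}


def write_surface_geojson(surface, path: str | Path) -> None:
    """Prediction surface as a GeoJSON point layer."""
    features = []
    for row in surface.table.itertuples():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
                "properties": {
                    "point_id": row.point_id,
                    "lake_id": row.lake_id,
                    "median": round(float(row.median), 6),
                    "lower": round(float(row.lower), 6),
                    "upper": round(float(row.upper), 6),
                    "width": round(float(row.width), 6),
                    "ever_detected": bool(row.ever_detected),
                },
            }
        )
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "year": surface.year,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
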