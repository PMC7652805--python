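"""Readers and writers for the pipeline's file formats.

Vector data is exchanged as GeoJSON (WGS84 lon/lat, the only CRS the
package works in); tabular data as headed CSV.  Every reader validates the
schema and reports offending rows by number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .effort import GearModel, EffortLayer, TRACK_COLUMNS
from .grid import StudyGrid, TimeFrame
from .uwc import DensitySurface, PersistenceLayer

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input file does not match its expected schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} (found {list(df.columns)})")


# ---------------------------------------------------------------- boundary

def read_boundary(path) -> BaseGeometry:
    """Read a (Multi)Polygon boundary from GeoJSON (Feature(Collection) or bare)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        if not geoms:
            raise SchemaError(f"{path}: empty FeatureCollection")
        if len(geoms) == 1:
            geom = geoms[0]
        else:
            from shapely.ops import unary_union

            geom = unary_union(geoms)
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise SchemaError(f"{path}: boundary must be (Multi)Polygon, got {geom.geom_type}")
    return geom


def write_boundary_geojson(geom: BaseGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "Feature", "properties": {}, "geometry": mapping(geom)},
            fh,
        )


def write_feature_collection(features: list[dict], path) -> None:
    """Write features (dicts with a shapely ``geometry`` + attributes) as GeoJSON."""
    out = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {k: v for k, v in f.items() if k != "geometry"},
                "geometry": mapping(f["geometry"]),
            }
            for f in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(out, fh)


def read_feature_collection(path) -> list[dict]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a FeatureCollection")
    return [
        {**f.get("properties", {}), "geometry": shape(f["geometry"])}
        for f in gj["features"]
    ]


# ------------------------------------------------------------------ tracks

def read_tracks_csv(path) -> pd.DataFrame:
    """Vessel tracks: vessel_id,timestamp(ISO-8601),lat,lon,speed_kn."""
    df = pd.read_csv(path, dtype={"vessel_id": str}, float_precision="round_trip")
    _require_columns(df, TRACK_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
        raise SchemaError(f"{path}: malformed timestamp at row(s) {rows}")
    df["timestamp"] = ts
    for col in ("lat", "lon", "speed_kn"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]
            raise SchemaError(f"{path}: non-numeric {col} at row(s) {rows}")
        df[col] = vals
    return df


def read_register_csv(path) -> pd.DataFrame:
    """Fleet register: vessel_id,loa_m,power_kw,gear,gear_secondary."""
    df = pd.read_csv(path, dtype={"vessel_id": str, "gear": str})
    _require_columns(df, ["vessel_id", "loa_m", "power_kw", "gear"], path)
    if df["vessel_id"].duplicated().any():
        dups = df.loc[df["vessel_id"].duplicated(), "vessel_id"].tolist()
        raise SchemaError(f"{path}: duplicate vessel_id {dups}")
    return df


def read_gear_models_csv(path) -> dict[str, GearModel]:
    """Gear models: gear,a,b,towed."""
    df = pd.read_csv(path, dtype={"gear": str})
    _require_columns(df, ["gear", "a", "b", "towed"], path)
    out = {}
    for r in df.itertuples():
        towed = str(r.towed).strip().lower() in ("true", "1", "yes")
        out[r.gear] = GearModel(r.gear, float(r.a), float(r.b), towed)
    return out


# ----------------------------------------------------------------- density

def read_density_csv(path) -> list[DensitySurface]:
    """Long-form densities: species,year,cell_id,density."""
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    _require_columns(df, ["species", "year", "cell_id", "density"], path)
    out = []
    for (species, year), g in df.groupby(["species", "year"], sort=True):
        out.append(
            DensitySurface(
                str(species),
                int(year),
                {int(c): float(v) for c, v in zip(g["cell_id"], g["density"])},
            )
        )
    return out


def write_density_csv(surfaces: list[DensitySurface], path) -> None:
    rows = [
        {"species": s.species, "year": s.year, "cell_id": c, "density": v}
        for s in surfaces
        for c, v in sorted(s.values.items())
    ]
    pd.DataFrame(rows, columns=["species", "year", "cell_id", "density"]).to_csv(
        path, index=False
    )


# ------------------------------------------------------------------ layers

def layers_to_frame(
    layers: dict[TimeFrame, EffortLayer], grid: StudyGrid
) -> pd.DataFrame:
    """Long-form effort table: cell_id,csquare,metric,year,quarter,value."""
    csq = grid.cells.set_index("cell_id")["csquare"]
    rows = []
    for frame in sorted(layers, key=str):
        layer = layers[frame]
        for cid, v in sorted(layer.values.items()):
            rows.append(
                {
                    "cell_id": cid,
                    "csquare": csq.loc[cid],
                    "metric": layer.metric,
                    "year": frame.year,
                    "quarter": frame.quarter if frame.kind == "quarter" else "",
                    "value": v,
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "csquare", "metric", "year", "quarter", "value"]
    )


def write_effort_csv(layers, grid: StudyGrid, path) -> None:
    layers_to_frame(layers, grid).to_csv(path, index=False)


def read_effort_csv(path) -> dict[TimeFrame, EffortLayer]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["cell_id", "metric", "year", "quarter", "value"], path)
    out: dict[TimeFrame, EffortLayer] = {}
    quarterly = df["quarter"].notna()
    df = df.assign(_q=df["quarter"].where(quarterly))
    for (metric, year, q), g in df.groupby(["metric", "year", "_q"], dropna=False):
        frame = (
            TimeFrame("year", int(year))
            if pd.isna(q)
            else TimeFrame("quarter", int(year), int(q))
        )
        out[frame] = EffortLayer(
            str(metric),
            frame,
            {int(c): float(v) for c, v in zip(g["cell_id"], g["value"])},
        )
    return out


def write_layer_geojson(
    values: dict[int, float], grid: StudyGrid, path, value_name: str = "value"
) -> None:
    """Export any per-cell layer as one GeoJSON feature per cell."""
    features = [
        {
            "cell_id": int(r.cell_id),
            "csquare": r.csquare,
            value_name: float(values.get(int(r.cell_id), 0.0)),
            "geometry": r.geometry,
        }
        for r in grid.cells.itertuples()
    ]
    write_feature_collection(features, path)


def write_grid_geojson(grid: StudyGrid, path) -> None:
    features = [
        {
            "cell_id": int(r.cell_id),
            "csquare": r.csquare,
            "area_km2": float(r.area_km2),
            "geometry": r.geometry,
        }
        for r in grid.cells.itertuples()
    ]
    write_feature_collection(features, path)


def write_pi_csv(layers: list[PersistenceLayer], path) -> None:
    rows = [
        {"cell_id": c, "species": l.species, "pi": v}
        for l in layers
        for c, v in sorted(l.pi.items())
    ]
    pd.DataFrame(rows, columns=["cell_id", "species", "pi"]).to_csv(path, index=False)


def read_pi_csv(path) -> list[PersistenceLayer]:
    df = pd.read_csv(path, dtype={"species": str}, float_precision="round_trip")
    _require_columns(df, ["cell_id", "species", "pi"], path)
    return [
        PersistenceLayer(
            str(species), [], {int(c): float(v) for c, v in zip(g["cell_id"], g["pi"])}
        )
        for species, g in df.groupby("species")
    ]


def write_fuzzy_csv(overlays: dict, species: str, metric: str, grid: StudyGrid, path) -> None:
    """Fuzzy overlay export: cell_id,year,quarter,species,metric,fuzzy_value."""
    rows = []
    for frame in sorted(overlays, key=str):
        for cid, mu in sorted(overlays[frame].memberships.items()):
            rows.append(
                {
                    "cell_id": cid,
                    "year": frame.year,
                    "quarter": frame.quarter if frame.kind == "quarter" else "",
                    "species": species,
                    "metric": metric,
                    "fuzzy_value": mu,
                }
            )
    pd.DataFrame(
        rows, columns=["cell_id", "year", "quarter", "species", "metric", "fuzzy_value"]
    ).to_csv(path, index=False)


def write_stats_csv(stats: dict, path) -> None:
    pd.DataFrame([stats]).to_csv(path, index=False)
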