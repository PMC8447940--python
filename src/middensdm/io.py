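"""File adapters: rasters, vectors, point clouds, tables, manifests.

All formats are plain text so runs are diffable and portable:

* rasters — ESRI ASCII grid (``.asc``) with a small JSON sidecar carrying
  the variable name, units and CRS tag;
* vectors — GeoJSON ``FeatureCollection`` per feature class;
* point clouds — the XYZC CSV dialect: columns ``x,y,z,class`` with class
  in {ground, vegetation, unclassified};
* tables — CSV with full decimal precision;
* stacks — a JSON manifest listing layer names, order and the grid spec.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .cloud import CLASS_NAMES, CLASSES, PointCloud
from .features import FEATURE_CLASSES, FeatureSet
from .grids import DEFAULT_CRS, GridSpec, RasterGrid
from .rasters import PredictorStack

__all__ = [
    "write_ascii_grid", "read_ascii_grid",
    "write_features", "read_features",
    "write_cloud_csv", "read_cloud_csv",
    "write_points_csv", "read_points_csv",
    "write_sample_table", "read_sample_table",
    "write_stack", "read_stack",
]

NODATA = -9999.0


class ParseError(ValueError):
    pass


# -- rasters ----------------------------------------------------------------


def write_ascii_grid(raster: RasterGrid, path: str) -> None:
    spec = raster.spec
    vals = np.where(np.isnan(raster.values), NODATA, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_x!r}\n")
        fh.write(f"yllcorner {spec.origin_y - spec.extent_y!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    with open(path + ".json", "w") as fh:
        json.dump({"name": raster.name, "units": raster.units,
                   "crs": spec.crs}, fh)


def read_ascii_grid(path: str) -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(header) < 6 and not _is_number(parts[0]):
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: malformed header line")
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing header field '{key}'")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.asarray(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ParseError(
            f"{path}: data shape {values.shape} != ({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    meta = {"name": "value", "units": "", "crs": DEFAULT_CRS}
    if os.path.exists(path + ".json"):
        with open(path + ".json") as fh:
            meta.update(json.load(fh))
    spec = GridSpec(origin_x=header["xllcorner"],
                    origin_y=header["yllcorner"] + n_rows * cell,
                    cell_size=cell, n_rows=n_rows, n_cols=n_cols,
                    crs=meta["crs"])
    return RasterGrid(spec, values, name=meta["name"], units=meta["units"])


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# -- vectors ----------------------------------------------------------------


def write_features(features: FeatureSet, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name in FEATURE_CLASSES:
        coll = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "properties": {"class": name},
                 "geometry": mapping(g)}
                for g in features.classes.get(name, [])
            ],
        }
        with open(os.path.join(out_dir, f"{name}.geojson"), "w") as fh:
            json.dump(coll, fh)


def read_features(in_dir: str) -> FeatureSet:
    classes: dict[str, list] = {}
    for name in FEATURE_CLASSES:
        path = os.path.join(in_dir, f"{name}.geojson")
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing feature class file: {path}")
        with open(path) as fh:
            try:
                coll = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: {exc}") from None
        classes[name] = [shape(f["geometry"]) for f in coll.get("features", [])]
    return FeatureSet(classes)


def read_polygon_geojson(path: str):
    """First polygon geometry in a GeoJSON file (Feature or collection)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in obj["features"]]
    elif obj.get("type") == "Feature":
        geoms = [shape(obj["geometry"])]
    else:
        geoms = [shape(obj)]
    polys = [g for g in geoms if g.geom_type in ("Polygon", "MultiPolygon")]
    if not polys:
        raise ParseError(f"{path}: no polygon geometry found")
    return polys[0]


def write_polygon_geojson(polygon, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "properties": {},
                   "geometry": mapping(polygon)}, fh)


# -- point clouds -----------------------------------------------------------


def write_cloud_csv(cloud: PointCloud, path: str) -> None:
    df = pd.DataFrame({
        "x": cloud.x, "y": cloud.y, "z": cloud.z,
        "class": [CLASS_NAMES[int(k)] for k in cloud.klass],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_cloud_csv(path: str) -> PointCloud:
    df = pd.read_csv(path)
    required = {"x", "y", "z", "class"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: XYZC CSV needs columns {sorted(required)}")
    tokens = df["class"].astype(str)
    unknown = sorted(set(tokens) - set(CLASSES))
    if unknown:
        raise ParseError(f"{path}: unknown class token '{unknown[0]}'")
    klass = tokens.map(CLASSES).to_numpy(dtype=np.int8)
    return PointCloud(df["x"].to_numpy(), df["y"].to_numpy(),
                      df["z"].to_numpy(), klass)


# -- point tables -----------------------------------------------------------


def write_points_csv(points: pd.DataFrame, path: str) -> None:
    points.to_csv(path, index=False, float_format="%.17g")


def read_points_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("x", "y"):
        if needed not in cols:
            raise ParseError(f"{path}: points CSV needs an '{needed}' column")
    out = pd.DataFrame({"x": df[cols["x"]], "y": df[cols["y"]]})
    if "label" in cols:
        out["label"] = df[cols["label"]]
    out.insert(0, "id", df[cols["id"]] if "id" in cols
               else np.arange(len(df)))
    return out


def write_sample_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_sample_table(path: str) -> pd.DataFrame:
    """Load a sample-table CSV.

    Accepts both this package's layout (id,x,y,label,weight,layers...) and
    the deposited presence/absence export layout, where the response column
    may be named like RESPONSE/PRESENCE and coordinates X/Y; columns are
    normalized to lower-case metadata names, predictor columns untouched.
    """
    df = pd.read_csv(path)
    rename = {}
    for c in df.columns:
        lc = c.strip().lower()
        if lc in ("id", "pointid", "objectid"):
            rename[c] = "id"
        elif lc in ("x", "easting", "x_coord"):
            rename[c] = "x"
        elif lc in ("y", "northing", "y_coord"):
            rename[c] = "y"
        elif lc in ("label", "response", "presence", "pres_abs"):
            rename[c] = "label"
        elif lc == "weight":
            rename[c] = "weight"
    df = df.rename(columns=rename)
    if "label" not in df.columns:
        raise ParseError(f"{path}: no presence/absence label column found")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    return df


# -- stacks -----------------------------------------------------------------


def write_stack(stack: PredictorStack, out_dir: str,
                manifest_name: str = "stack.json") -> str:
    os.makedirs(out_dir, exist_ok=True)
    layers = []
    for name, raster in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(raster, os.path.join(out_dir, fname))
        layers.append({"name": name, "file": fname, "units": raster.units})
    spec = stack.spec
    manifest = {
        "grid": {"origin_x": spec.origin_x, "origin_y": spec.origin_y,
                 "cell_size": spec.cell_size, "n_rows": spec.n_rows,
                 "n_cols": spec.n_cols, "crs": spec.crs},
        "layers": layers,
    }
    path = os.path.join(out_dir, manifest_name)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def read_stack(manifest_path: str) -> PredictorStack:
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = os.path.dirname(manifest_path)
    rasters = []
    for layer in manifest["layers"]:
        raster = read_ascii_grid(os.path.join(base, layer["file"]))
        raster.name = layer["name"]
        raster.units = layer.get("units", raster.units)
        rasters.append(raster)
    return PredictorStack(rasters)
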