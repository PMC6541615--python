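"""File I/O for pipeline artifacts.

Formats: specimen tables and matrices as delimiter-separated text, rasters
as ESRI ASCII grids, scene geometry as GeoJSON, results as JSON.  All
writers are deterministic (fixed float formats, sorted keys) so a fixed
seed reproduces byte-identical bundles.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .raster import DisturbanceRaster
from .synthetic import (
    MIN_SIZE_CM,
    SPECIMEN_COLUMNS,
    SurveyScene,
    TrackLayout,
)

__all__ = [
    "write_specimens",
    "read_specimens",
    "SchemaError",
    "write_ascii_grid",
    "read_ascii_grid",
    "scene_to_geojson",
    "write_abundance",
    "write_units",
    "write_json",
]

log = logging.getLogger("benthograd")

_FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    """A specimen file does not match the expected schema."""


def write_specimens(table: pd.DataFrame, path) -> None:
    """Write a specimen table as CSV with the canonical header.

    Round-trips losslessly with :func:`read_specimens` (positions/sizes are
    quantised to 1e-6 by the generator).
    """
    table[list(SPECIMEN_COLUMNS)].to_csv(path, index=False, float_format=_FLOAT_FMT)


#: Column aliases accepted by the ingest adapter for externally produced
#: annotation tables (image-annotation platform exports).
_ALIASES = {
    "specimen_id": ("specimen_id", "id", "annotation_id", "label_id"),
    "x_m": ("x_m", "x", "pos_x", "easting_m"),
    "y_m": ("y_m", "y", "pos_y", "northing_m"),
    "morphospecies": ("morphospecies", "msp", "label", "taxon"),
    "group": ("group", "taxon_group", "higher_taxon"),
    "feeding": ("feeding", "feeding_group", "feeding_mode"),
    "size_cm": ("size_cm", "size", "length_cm"),
}


def read_specimens(path, min_size_cm: float = MIN_SIZE_CM) -> pd.DataFrame:
    """Read and validate a specimen table.

    Column aliases are mapped to the canonical schema; rows with non-numeric
    coordinates are collected into ``df.attrs["bad_rows"]`` (1-based line
    numbers) and specimens at or below the minimum dimension are excluded
    with a logged count (``df.attrs["n_below_min_size"]``).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for canon, aliases in _ALIASES.items():
        for a in aliases:
            if a in raw.columns:
                rename[a] = canon
                break
    raw = raw.rename(columns=rename)
    missing = [c for c in SPECIMEN_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    bad_rows = []
    num = {}
    for col in ("x_m", "y_m", "size_cm"):
        v = pd.to_numeric(raw[col], errors="coerce")
        bad_rows.extend((np.flatnonzero(v.isna() & (raw[col] != "")) + 2).tolist())
        bad_rows.extend((np.flatnonzero(raw[col] == "") + 2).tolist())
        num[col] = v
    bad_rows = sorted(set(bad_rows))
    df = pd.DataFrame(
        {
            "specimen_id": raw["specimen_id"],
            "x_m": num["x_m"],
            "y_m": num["y_m"],
            "morphospecies": raw["morphospecies"],
            "group": raw["group"],
            "feeding": raw["feeding"],
            "size_cm": num["size_cm"],
        }
    )
    ok = ~df[["x_m", "y_m", "size_cm"]].isna().any(axis=1)
    df = df[ok]
    small = df["size_cm"] <= min_size_cm
    n_small = int(small.sum())
    if n_small:
        log.info("excluded %d specimens with dimension <= %g cm", n_small, min_size_cm)
    df = df[~small].reset_index(drop=True)
    if df["specimen_id"].duplicated().any():
        raise SchemaError("duplicate specimen ids")
    df.attrs["bad_rows"] = bad_rows
    df.attrs["n_below_min_size"] = n_small
    return df


def write_ascii_grid(path, origin, cell_size, values, nodata=-9999.0) -> None:
    """Write a 2-D array (row 0 = southern edge) as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:.1f}\n")
        for r in range(n_rows - 1, -1, -1):  # top row first
            fh.write(" ".join(_FLOAT_FMT % v for v in out[r]) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (origin, cell_size, values, nodata)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    data = np.loadtxt(lines[6:]).reshape(n_rows, n_cols)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return (
        (header["xllcorner"], header["yllcorner"]),
        header["cellsize"],
        data,
        nodata,
    )


def scene_to_geojson(scene: SurveyScene) -> dict:
    """Scene extent (Polygon) and track centrelines (LineStrings with width_m)."""
    ox, oy = scene.origin
    ring = [
        [ox, oy],
        [ox + scene.width, oy],
        [ox + scene.width, oy + scene.height],
        [ox, oy + scene.height],
        [ox, oy],
    ]
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"name": scene.name, "role": "extent",
                           "area_ha": scene.area_ha},
        }
    ]
    for i, line in enumerate(scene.tracks.centrelines):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": np.asarray(line).tolist(),
                },
                "properties": {"role": "track", "track": i,
                               "width_m": scene.tracks.width},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def scene_from_geojson(obj: dict) -> SurveyScene:
    extent = None
    lines, width = [], 8.0
    for feat in obj["features"]:
        props = feat.get("properties", {})
        if props.get("role") == "extent":
            extent = feat
        elif props.get("role") == "track":
            lines.append(np.asarray(feat["geometry"]["coordinates"], dtype=float))
            width = float(props.get("width_m", width))
    if extent is None:
        raise SchemaError("GeoJSON has no extent polygon")
    ring = np.asarray(extent["geometry"]["coordinates"][0], dtype=float)
    ox, oy = ring.min(axis=0)
    w, h = ring.max(axis=0) - ring.min(axis=0)
    return SurveyScene(
        name=extent["properties"].get("name", "scene"),
        width=float(w),
        height=float(h),
        origin=(float(ox), float(oy)),
        tracks=TrackLayout(centrelines=tuple(lines), width=width)
        if lines
        else TrackLayout(),
    )


def write_units(units, path) -> None:
    """Unit membership table: unit_id, level, replicate, cell_index."""
    rows = []
    for u in units:
        for c in u.cell_indices:
            rows.append((u.unit_id, u.level, u.replicate, int(c)))
    pd.DataFrame(rows, columns=["unit_id", "level", "replicate", "cell_index"]).to_csv(
        path, index=False
    )


def write_abundance(abund, path) -> None:
    """Wide abundance matrix with unit metadata columns first."""
    out = abund.meta.join(abund.counts)
    out.to_csv(path, float_format=_FLOAT_FMT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
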