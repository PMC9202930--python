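"""Readers and writers for the text formats the pipeline touches.

Rasters are stored as ESRI ASCII grids (``.asc``) — a plain-text,
georeferenced single-band format readable by every common GIS.  Vector data
(roads, protected areas) travel as GeoJSON; points and road-kill records as
CSV with headers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiLineString, MultiPolygon, Polygon, shape, mapping

from .raster import RasterGrid
from .vector import OccurrenceSet, ProtectedAreas, RoadKillTable, RoadNetwork, SEASONS

__all__ = [
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
    "read_vector",
    "write_vector",
    "read_roadkill",
    "rasterize",
]

_NODATA = -9999.0


def write_raster(grid: RasterGrid, path) -> Path:
    """Write a grid as an ESRI ASCII raster with a declared nodata value."""
    path = Path(path)
    vals = grid.values.copy()
    vals[grid.nodata_mask] = _NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {float(grid.origin[0])!r}\n"
        f"yllcorner {float(grid.origin[1] - grid.n_rows * grid.cell_size)!r}\n"
        f"cellsize {float(grid.cell_size)!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
    path.write_text(header + body + "\n")
    return path


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII raster; cells equal to the declared nodata are masked."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "dx", "dy", "nodata_value",
    }:
        key, val = lines[i].split(maxsplit=1)
        header[key.lower()] = float(val)
        i += 1
    if "dx" in header or "dy" in header:
        raise ValueError("non-square cells (dx/dy header) are not supported")
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"missing required header field {req!r} in {path}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"raster body shape {vals.shape} does not match header")
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    vals = vals.copy()
    vals[mask] = 0.0
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * header["cellsize"])
    return RasterGrid(values=vals, cell_size=header["cellsize"], origin=origin, nodata_mask=mask)


def read_points(path, species: str | None = None) -> OccurrenceSet:
    """Read x,y[,species,...] CSV into an OccurrenceSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"points file not found: {path}")
    df = pd.read_csv(path)
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(
            f"points file {path} lacks required coordinate column(s) {sorted(missing)}; "
            f"found columns {list(df.columns)}"
        )
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
    if len(df) == 0:
        warnings.warn(f"points file {path} yielded no rows", stacklevel=2)
    try:
        pts = df[["x", "y"]].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric coordinates in {path}: {exc}") from exc
    label = species or (str(df["species"].iloc[0]) if "species" in df.columns and len(df) else "")
    return OccurrenceSet(species=label, points=pts)


def write_points(occ: OccurrenceSet, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"x": occ.x, "y": occ.y})
    df.insert(0, "species", occ.species)
    df.to_csv(path, index=False)
    return path


def read_vector(path, kind: str):
    """Read a GeoJSON file as a RoadNetwork (kind='lines') or ProtectedAreas (kind='polygons')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"vector file not found: {path}")
    gj = json.loads(path.read_text())
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    geoms, cats = [], []
    for feat in feats:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        props = feat.get("properties") or {}
        parts = list(geom.geoms) if isinstance(geom, (MultiLineString, MultiPolygon)) else [geom]
        for part in parts:
            geoms.append(part)
            cats.append(str(props.get("category", "CA")))
    if kind == "lines":
        bad = [g.geom_type for g in geoms if not isinstance(g, LineString)]
        if bad:
            raise ValueError(f"requested lines but found geometry type(s) {sorted(set(bad))}")
        return RoadNetwork(polylines=[np.asarray(g.coords) for g in geoms])
    if kind == "polygons":
        bad = [g.geom_type for g in geoms if not isinstance(g, Polygon)]
        if bad:
            raise ValueError(f"requested polygons but found geometry type(s) {sorted(set(bad))}")
        return ProtectedAreas(polygons=geoms, categories=cats)
    raise ValueError(f"kind must be 'lines' or 'polygons', got {kind!r}")


def write_vector(obj, path) -> Path:
    path = Path(path)
    if isinstance(obj, RoadNetwork):
        feats = [
            {"type": "Feature", "properties": {}, "geometry": mapping(LineString(p))}
            for p in obj.polylines
        ]
    elif isinstance(obj, ProtectedAreas):
        feats = [
            {"type": "Feature", "properties": {"category": cat}, "geometry": mapping(poly)}
            for poly, cat in zip(obj.polygons, obj.categories)
        ]
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
    return path


def read_roadkill(path, species: str | None = None) -> RoadKillTable:
    """Read species,season,year,count CSV rows into a RoadKillTable."""
    df = pd.read_csv(path)
    required = {"season", "year", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"road-kill file needs columns {sorted(required)}")
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
    years = sorted(df["year"].unique())
    counts = np.zeros((len(SEASONS), len(years)), dtype=int)
    for _, row in df.iterrows():
        counts[SEASONS.index(row["season"]), years.index(row["year"])] += int(row["count"])
    label = species or (str(df["species"].iloc[0]) if "species" in df.columns and len(df) else "")
    return RoadKillTable(species=label, counts=counts, years=[int(y) for y in years])


def rasterize(geoms, template: RasterGrid) -> RasterGrid:
    """Burn geometries into a binary grid: cells touched by geometry get 1.

    Polygons touch a cell when their intersection has positive area; lines
    when the clipped length is positive.  Disjoint geometry yields an
    all-zero grid with a warning.
    """
    if isinstance(geoms, RoadNetwork):
        shapes = geoms.as_linestrings()
        mode = "lines"
    elif isinstance(geoms, ProtectedAreas):
        shapes = list(geoms.polygons)
        mode = "polygons"
    else:
        raise TypeError(f"cannot rasterize {type(geoms).__name__}")
    out = np.zeros(template.shape, dtype=float)
    if not shapes:
        return template.like(out)
    cs = template.cell_size
    xmin, ymin, xmax, ymax = template.extent
    hit_any = False
    for geom in shapes:
        gx0, gy0, gx1, gy1 = geom.bounds
        if gx1 < xmin or gx0 > xmax or gy1 < ymin or gy0 > ymax:
            continue
        # candidate cell window from geometry bounds
        c0 = max(0, int(np.floor((gx0 - xmin) / cs)))
        c1 = min(template.n_cols - 1, int(np.floor((gx1 - xmin) / cs)))
        r0 = max(0, int(np.floor((ymax - gy1) / cs)))
        r1 = min(template.n_rows - 1, int(np.floor((ymax - gy0) / cs)))
        rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        rows, cols = rows.ravel(), cols.ravel()
        boxes = shapely.box(
            xmin + cols * cs, ymax - (rows + 1) * cs, xmin + (cols + 1) * cs, ymax - rows * cs
        )
        inter = shapely.intersection(geom, boxes)
        if mode == "polygons":
            hit = shapely.area(inter) > 1e-9 * cs * cs
        else:
            hit = shapely.length(inter) > 1e-9 * cs
        if hit.any():
            hit_any = True
            out[rows[hit], cols[hit]] = 1.0
    if not hit_any:
        warnings.warn("geometries are disjoint from the template extent", stacklevel=2)
    return template.like(out)
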