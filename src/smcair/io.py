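"""File I/O: rasters (Esri ASCII grid, single-band GeoTIFF), vectors
(GeoJSON) and residence tables (CSV).

The ASCII-grid path is fully text-based and is what the test fixtures use;
the GeoTIFF path writes ModelPixelScale/ModelTiepoint tags via tifffile so
outputs open georegistered in desktop GIS.  Raster ``kind``/``nodata``/CRS
metadata rides in a JSON sidecar for .asc and in the image description tag
for .tif.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UnsupportedFormatError, ValidationError
from .geo_core import FeatureSet, GridSpec, Raster, ResidenceRecord

_GEOJSON_TYPES = {"point": "Point", "polyline": "LineString", "polygon": "Polygon"}
_GEOJSON_TYPES_INV = {v: k for k, v in _GEOJSON_TYPES.items()}

# TIFF tag codes for georeferencing
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_raster(path: str | Path, raster: Raster) -> Path:
    path = Path(path)
    if path.suffix == ".asc":
        _write_asc(path, raster)
    elif path.suffix in (".tif", ".tiff"):
        _write_tif(path, raster)
    else:
        raise UnsupportedFormatError(f"unknown raster extension {path.suffix!r}")
    return path

def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    if path.suffix == ".asc":
        return _read_asc(path)
    if path.suffix in (".tif", ".tiff"):
        return _read_tif(path)
    raise UnsupportedFormatError(f"unknown raster extension {path.suffix!r}")


def _meta(raster: Raster) -> dict:
    return {"kind": raster.kind, "nodata": raster.nodata, "crs": raster.grid.crs}


def _write_asc(path: Path, r: Raster) -> None:
    g = r.grid
    is_int = np.issubdtype(r.values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_min!r}\n")
        fh.write(f"yllcorner {g.y_min!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {int(r.nodata) if is_int else r.nodata!r}\n")
        fmt = "%d" if is_int else "%.17g"
        np.savetxt(fh, r.values, fmt=fmt)
    path.with_suffix(".asc.aux.json").write_text(json.dumps(_meta(r)))


def _read_asc(path: Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    meta_path = path.with_suffix(".asc.aux.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    grid = GridSpec(x_min=header["xllcorner"],
                    y_max=header["yllcorner"] + n_rows * cell,
                    n_rows=n_rows, n_cols=n_cols, cell_size=cell,
                    crs=meta.get("crs", "local-metric"))
    kind = meta.get("kind", "continuous")
    if kind in ("class", "categorical", "binary"):
        values = values.astype(np.int64)
    return Raster(grid=grid, values=values,
                  nodata=meta.get("nodata", header["nodata_value"]), kind=kind)


def _write_tif(path: Path, r: Raster) -> None:
    import tifffile

    g = r.grid
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_min, g.y_max, 0.0)),
    ]
    values = r.values
    if np.issubdtype(values.dtype, np.integer):
        values = values.astype(np.int32)
    else:
        values = values.astype(np.float64)
    tifffile.imwrite(path, values, extratags=extratags,
                     description=json.dumps(_meta(r)))


def _read_tif(path: Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        scale = page.tags[_MODEL_PIXEL_SCALE].value
        tie = page.tags[_MODEL_TIEPOINT].value
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    n_rows, n_cols = values.shape
    grid = GridSpec(x_min=tie[3], y_max=tie[4], n_rows=n_rows, n_cols=n_cols,
                    cell_size=scale[0], crs=meta.get("crs", "local-metric"))
    kind = meta.get("kind", "continuous")
    if kind in ("class", "categorical", "binary"):
        values = values.astype(np.int64)
    return Raster(grid=grid, values=values,
                  nodata=meta.get("nodata", -9999.0), kind=kind)


def write_featureset(path: str | Path, fs: FeatureSet) -> Path:
    path = Path(path)
    if path.suffix not in (".geojson", ".json"):
        raise UnsupportedFormatError(f"unknown vector extension {path.suffix!r}")
    features = []
    for geom, attrs in zip(fs.geometries, fs.attributes):
        if fs.geometry_type == "point":
            coords = list(geom[0])
        elif fs.geometry_type == "polyline":
            coords = geom.tolist()
        else:
            coords = [geom.tolist()]  # single exterior ring
        features.append({
            "type": "Feature",
            "geometry": {"type": _GEOJSON_TYPES[fs.geometry_type], "coordinates": coords},
            "properties": attrs,
        })
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_featureset(path: str | Path,
                    expect_type: str | None = None) -> FeatureSet:
    path = Path(path)
    if path.suffix not in (".geojson", ".json"):
        raise UnsupportedFormatError(f"unknown vector extension {path.suffix!r}")
    doc = json.loads(path.read_text())
    geoms, attrs, gtype = [], [], None
    for feat in doc.get("features", []):
        geo = feat["geometry"]
        try:
            this_type = _GEOJSON_TYPES_INV[geo["type"]]
        except KeyError:
            raise ValidationError(f"unsupported GeoJSON geometry {geo['type']!r}")
        if gtype is None:
            gtype = this_type
        elif this_type != gtype:
            raise ValidationError("mixed geometry types in one layer")
        c = geo["coordinates"]
        if this_type == "point":
            geoms.append(np.array([c], dtype=float))
        elif this_type == "polyline":
            geoms.append(np.array(c, dtype=float))
        else:
            geoms.append(np.array(c[0], dtype=float))
        attrs.append(dict(feat.get("properties") or {}))
    if gtype is None:
        gtype = expect_type or "point"
        if expect_type is None:
            raise ValidationError(f"{path} contains no features; pass expect_type")
    if expect_type is not None and gtype != expect_type:
        raise ValidationError(f"expected {expect_type} layer, found {gtype}")
    return FeatureSet(geometry_type=gtype, geometries=geoms, attributes=attrs)


RESIDENCE_COLUMNS = ["id", "x", "y", "group", "birth_day", "postal_centroid_id"]


def write_residences(path: str | Path, residences: Sequence[ResidenceRecord]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESIDENCE_COLUMNS)
        for r in residences:
            w.writerow([r.id, repr(r.x), repr(r.y), r.group, r.birth_day,
                        r.postal_centroid_id])
    return path


def read_residences(path: str | Path,
                    bounds: tuple[float, float, float, float] | None = None
                    ) -> list[ResidenceRecord]:
    """Load and validate a residence CSV.

    Rows with unknown group labels are reported together in one
    :class:`ValidationError`; with ``bounds`` given, records outside the
    study bounds are rejected the same way.
    """
    df = pd.read_csv(path, dtype={"id": str, "postal_centroid_id": str})
    missing = [c for c in RESIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"residence CSV missing columns {missing}")
    bad_rows = df.index[~df["group"].isin(["case", "control"])].tolist()
    if bad_rows:
        labels = df.loc[bad_rows, "group"].tolist()
        raise ValidationError(
            f"bad group labels at rows {bad_rows}: {labels} "
            "(expected 'case' or 'control')")
    if bounds is not None:
        x_min, y_min, x_max, y_max = bounds
        out = df.index[(df.x < x_min) | (df.x > x_max)
                       | (df.y < y_min) | (df.y > y_max)].tolist()
        if out:
            raise ValidationError(f"residences outside study bounds at rows {out}")
    return [ResidenceRecord(id=str(r.id), x=float(r.x), y=float(r.y),
                            group=str(r.group), birth_day=int(r.birth_day),
                            postal_centroid_id=str(r.postal_centroid_id))
            for r in df.itertuples(index=False)]
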