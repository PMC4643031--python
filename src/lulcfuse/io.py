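"""Raster and sample-table I/O.

Rasters are written as tiled GeoTIFFs via :mod:`tifffile`: georeferencing is
carried in the standard ``ModelPixelScale``/``ModelTiepoint`` tags and a JSON
``ImageDescription`` records the CRS string, nodata value, band names and
composite dates.  Label maps are 8-bit unsigned with a nodata code;
probability and reflectance rasters are 32-bit float.  Sample tables are CSV
with columns ``x, y`` (or ``row, col``), ``class_name`` and an optional
``split`` column.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import (
    CUBE_BANDS,
    GeoTransform,
    IDENTITY_TRANSFORM,
    ClassScheme,
    LULCMap,
    ProbabilityCube,
    SampleSet,
    TimeSeriesCube,
)

log = logging.getLogger(__name__)

__all__ = [
    "write_raster",
    "read_raster",
    "write_map",
    "read_map",
    "write_probability_cube",
    "read_probability_cube",
    "write_cube",
    "read_cube",
    "read_raster_stack",
    "read_samples",
    "write_samples",
    "rowcol_to_xy",
    "xy_to_rowcol",
]

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922


def rowcol_to_xy(
    rows: np.ndarray, cols: np.ndarray, gt: GeoTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre map coordinates of 0-based (row, col) indices."""
    x0, dx, rx, y0, ry, dy = gt
    c = np.asarray(cols) + 0.5
    r = np.asarray(rows) + 0.5
    return x0 + c * dx + r * rx, y0 + c * ry + r * dy


def xy_to_rowcol(
    xs: np.ndarray, ys: np.ndarray, gt: GeoTransform
) -> tuple[np.ndarray, np.ndarray]:
    """0-based (row, col) of map coordinates; inverse of :func:`rowcol_to_xy`."""
    x0, dx, rx, y0, ry, dy = gt
    a = np.array([[dx, rx], [ry, dy]], dtype=float)
    inv = np.linalg.inv(a)
    dxv = np.asarray(xs, dtype=float) - x0
    dyv = np.asarray(ys, dtype=float) - y0
    c = inv[0, 0] * dxv + inv[0, 1] * dyv
    r = inv[1, 0] * dxv + inv[1, 1] * dyv
    return np.floor(r).astype(np.intp), np.floor(c).astype(np.intp)


def _geo_extratags(gt: GeoTransform):
    x0, dx, rx, y0, ry, dy = gt
    if rx == 0.0 and ry == 0.0:
        scale = (abs(dx), abs(dy), 0.0)
        tie = (0.0, 0.0, 0.0, x0, y0, 0.0)
        return [
            (_GEOTIFF_PIXELSCALE, "d", 3, scale, True),
            (_GEOTIFF_TIEPOINT, "d", 6, tie, True),
        ]
    return []  # rotated grids: JSON description only


def _description(meta: dict) -> str:
    return json.dumps({"lulcfuse": meta})


def _parse_description(desc: str | None) -> dict:
    if not desc:
        return {}
    try:
        payload = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    return payload.get("lulcfuse", {}) if isinstance(payload, dict) else {}


def write_raster(
    path: str | Path,
    data: np.ndarray,
    geotransform: GeoTransform = IDENTITY_TRANSFORM,
    crs: str = "",
    nodata: float | int | None = None,
    band_names: Sequence[str] | None = None,
    extra_meta: dict | None = None,
) -> None:
    """Write a 2-D or 3-D ``(band, row, col)`` array as a GeoTIFF."""
    data = np.asarray(data)
    meta = {
        "geotransform": list(geotransform),
        "crs": crs,
        "nodata": nodata,
        "band_names": list(band_names) if band_names is not None else None,
    }
    if extra_meta:
        meta.update(extra_meta)
    tifffile.imwrite(
        str(path),
        data,
        description=_description(meta),
        extratags=_geo_extratags(geotransform),
        photometric="minisblack",
    )


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a raster and its metadata dict (geotransform, crs, nodata, ...)."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        meta = _parse_description(page.description)
        if "geotransform" not in meta:
            # fall back to bare GeoTIFF tags
            tags = page.tags
            scale = tags.valueof(_GEOTIFF_PIXELSCALE)
            tie = tags.valueof(_GEOTIFF_TIEPOINT)
            if scale is not None and tie is not None:
                meta["geotransform"] = [
                    float(tie[3]),
                    float(scale[0]),
                    0.0,
                    float(tie[4]),
                    0.0,
                    -float(scale[1]),
                ]
            else:
                meta["geotransform"] = list(IDENTITY_TRANSFORM)
        meta.setdefault("crs", "")
        meta.setdefault("nodata", None)
        meta.setdefault("band_names", None)
    meta["geotransform"] = tuple(float(v) for v in meta["geotransform"])
    return data, meta


def write_map(lulc: LULCMap, path: str | Path) -> None:
    """Write a label map as 8-bit GeoTIFF; refuses maps violating the scheme."""
    lulc.validate()
    codes = set(lulc.scheme.codes) | {
        lulc.scheme.unclassified_code,
        lulc.scheme.nodata_code,
    }
    if max(codes) > 255 or min(codes) < 0:
        raise ValueError("class codes do not fit 8-bit storage")
    write_raster(
        path,
        lulc.labels.astype(np.uint8),
        geotransform=lulc.geotransform,
        crs=lulc.crs,
        nodata=lulc.scheme.nodata_code,
        extra_meta={
            "kind": "lulc_map",
            "classes": [[c, n] for c, n in lulc.scheme.classes],
            "unclassified_code": lulc.scheme.unclassified_code,
            "nodata_code": lulc.scheme.nodata_code,
        },
    )


def read_map(path: str | Path, scheme: ClassScheme | None = None) -> LULCMap:
    data, meta = read_raster(path)
    if scheme is None:
        if "classes" in meta:
            scheme = ClassScheme(
                classes=tuple((int(c), str(n)) for c, n in meta["classes"]),
                unclassified_code=int(meta.get("unclassified_code", 0)),
                nodata_code=int(meta.get("nodata_code", 255)),
            )
        else:
            raise ValueError(f"{path}: no class scheme stored and none provided")
    lulc = LULCMap(
        labels=data.astype(np.int64),
        scheme=scheme,
        geotransform=meta["geotransform"],
        crs=meta.get("crs", ""),
    )
    lulc.validate()
    return lulc


def write_probability_cube(cube: ProbabilityCube, path: str | Path) -> None:
    cube.validate()
    if cube.probs.ndim != 3:
        raise ValueError("only (class, row, col) probability cubes are rasters")
    data = cube.probs.astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(-1.0))
    write_raster(
        path,
        data,
        geotransform=cube.geotransform,
        crs=cube.crs,
        nodata=-1.0,
        band_names=list(cube.scheme.names),
        extra_meta={
            "kind": "probability_cube",
            "classes": [[c, n] for c, n in cube.scheme.classes],
            "source": cube.source,
        },
    )


def read_probability_cube(
    path: str | Path, scheme: ClassScheme | None = None
) -> ProbabilityCube:
    data, meta = read_raster(path)
    if scheme is None:
        scheme = ClassScheme(
            classes=tuple((int(c), str(n)) for c, n in meta["classes"])
        )
    probs = data.astype(np.float64)
    probs[probs == meta.get("nodata", -1.0)] = np.nan
    cube = ProbabilityCube(
        probs=probs,
        scheme=scheme,
        source=meta.get("source", ""),
        geotransform=meta["geotransform"],
        crs=meta.get("crs", ""),
    )
    cube.validate()
    return cube


def write_cube(cube: TimeSeriesCube, path: str | Path) -> None:
    """Write a full time-series cube to a single multiband GeoTIFF."""
    data = cube.values.astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(-9999.0))
    write_raster(
        path,
        data,
        geotransform=cube.geotransform,
        crs=cube.crs,
        nodata=-9999.0,
        band_names=list(cube.bands),
        extra_meta={"kind": "time_series_cube", "dates": cube.dates.tolist()},
    )


def read_cube(path: str | Path) -> TimeSeriesCube:
    data, meta = read_raster(path)
    values = data.astype(np.float64)
    values[values == meta.get("nodata", -9999.0)] = np.nan
    cube = TimeSeriesCube(
        values=values,
        bands=tuple(meta["band_names"]),
        dates=np.asarray(meta["dates"], dtype=float),
        geotransform=meta["geotransform"],
        crs=meta.get("crs", ""),
    )
    cube.validate()
    return cube


def read_raster_stack(
    paths: Sequence[str | Path],
    band_names: Sequence[str],
    dates: Sequence[float] | None = None,
) -> TimeSeriesCube:
    """Assemble per-composite multiband rasters into a validated cube.

    Each path holds one composite with ``len(band_names)`` planes.  All files
    must share grid shape and geotransform; the offending file is named on
    mismatch.  Composite dates come from each file's metadata (``date`` key)
    unless supplied explicitly.
    """
    band_names = tuple(band_names)
    unknown = set(band_names) - set(CUBE_BANDS)
    if unknown:
        raise ValueError(f"unknown band names: {sorted(unknown)}")
    planes, metas = [], []
    for p in paths:
        data, meta = read_raster(p)
        if data.ndim == 2:
            data = data[None]
        if data.shape[0] != len(band_names):
            raise ValueError(
                f"{p}: expected {len(band_names)} bands, found {data.shape[0]}"
            )
        planes.append(data.astype(np.float64))
        metas.append(meta)
    ref_shape, ref_gt = planes[0].shape[1:], metas[0]["geotransform"]
    for p, arr, meta in zip(paths, planes, metas):
        if arr.shape[1:] != ref_shape:
            raise ValueError(
                f"grid mismatch: {p} has shape {arr.shape[1:]}, expected {ref_shape}"
            )
        if not np.allclose(meta["geotransform"], ref_gt):
            raise ValueError(f"grid mismatch: {p} has a different geotransform")
    values = np.stack(planes)
    for i, meta in enumerate(metas):
        nod = meta.get("nodata")
        if nod is not None:
            values[i][values[i] == nod] = np.nan
    if dates is None:
        dates = []
        for p, meta in zip(paths, metas):
            if "date" not in meta:
                raise ValueError(f"{p}: no composite date in metadata")
            dates.append(float(meta["date"]))
    cube = TimeSeriesCube(
        values=values,
        bands=band_names,
        dates=np.asarray(dates, dtype=float),
        geotransform=ref_gt,
        crs=metas[0].get("crs", ""),
    ).sorted_by_date()
    if "qa" in band_names:
        qa = cube.band("qa")
        finite = qa[np.isfinite(qa)]
        bad = finite[~np.isin(finite, (0, 1, 2, 3))]
        if bad.size:
            # locate the offending file for the error message
            for p, plane in zip(paths, cube.values):
                q = plane[band_names.index("qa")]
                qf = q[np.isfinite(q)]
                off = qf[~np.isin(qf, (0, 1, 2, 3))]
                if off.size:
                    raise ValueError(
                        f"{p}: qa band contains invalid value {off.flat[0]:g}"
                    )
    cube.validate()
    return cube


def read_samples(
    csv_path: str | Path,
    scheme: ClassScheme,
    geotransform: GeoTransform | None = None,
) -> SampleSet:
    """Read a labelled reference-point CSV.

    Accepts either pixel coordinates (``row, col``) or map coordinates
    (``x, y`` — requires ``geotransform``).  Unknown class names raise with
    the offenders listed; duplicated coordinates are retained with a logged
    warning.  Per-class counts are logged.
    """
    df = pd.read_csv(csv_path)
    if "class_name" not in df.columns:
        raise ValueError(f"{csv_path}: missing 'class_name' column")
    names = set(scheme.names)
    offenders = sorted(set(df["class_name"]) - names)
    if offenders:
        raise ValueError(f"{csv_path}: unknown class names: {offenders}")
    codes = df["class_name"].map({n: scheme.code_of(n) for n in names}).to_numpy()
    xs = ys = None
    if {"row", "col"}.issubset(df.columns):
        rows = df["row"].to_numpy(dtype=np.intp)
        cols = df["col"].to_numpy(dtype=np.intp)
        if {"x", "y"}.issubset(df.columns):
            xs, ys = df["x"].to_numpy(float), df["y"].to_numpy(float)
    elif {"x", "y"}.issubset(df.columns):
        if geotransform is None:
            raise ValueError(
                f"{csv_path}: has x/y coordinates but no geotransform was given"
            )
        xs, ys = df["x"].to_numpy(float), df["y"].to_numpy(float)
        rows, cols = xy_to_rowcol(xs, ys, geotransform)
    else:
        raise ValueError(f"{csv_path}: needs 'row'/'col' or 'x'/'y' columns")
    dup = pd.DataFrame({"r": rows, "c": cols}).duplicated().sum()
    if dup:
        warnings.warn(f"{csv_path}: {dup} duplicated coordinates retained")
    split = None
    if "split" in df.columns:
        split = df["split"].to_numpy(dtype=object)
    ss = SampleSet(rows=rows, cols=cols, codes=codes, split=split, xs=xs, ys=ys)
    log.info("read %d samples: %s", len(ss), ss.class_counts(scheme))
    return ss


def write_samples(
    samples: SampleSet,
    scheme: ClassScheme,
    csv_path: str | Path,
    geotransform: GeoTransform | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "row": samples.rows,
            "col": samples.cols,
            "class_name": [scheme.name_of(c) for c in samples.codes],
        }
    )
    if geotransform is not None:
        xs, ys = rowcol_to_xy(samples.rows, samples.cols, geotransform)
        df.insert(0, "y", ys)
        df.insert(0, "x", xs)
    if samples.split is not None:
        df["split"] = samples.split
    df.to_csv(csv_path, index=False)
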