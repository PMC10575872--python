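"""File I/O: single-band rasters, vector export, flat config files.

Rasters are written as single-band TIFF with all georeferencing and
provenance (band, date, nodata, pixel size, origin) carried in a JSON
document in the TIFF ImageDescription tag.  Real-data readers must accept
integer-scaled surface reflectance; :func:`read_raster` applies a
metadata-declared ``scale``/``offset`` so downstream code always sees 0-1
floating-point reflectance.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import tifffile
from shapely.geometry import box, mapping
from shapely.ops import unary_union

__all__ = [
    "write_raster",
    "read_raster",
    "mask_to_polygons",
    "mask_to_geojson",
    "write_config",
    "read_config",
]


def write_raster(
    path: str | Path,
    array: np.ndarray,
    *,
    nodata: float | int | None = None,
    pixel_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
    band: str | None = None,
    date: _dt.date | str | None = None,
    extra: dict[str, Any] | None = None,
) -> Path:
    """Write a single-band raster with JSON metadata in the description tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta: dict[str, Any] = {
        "nodata": nodata,
        "pixel_size": pixel_size,
        "origin": list(origin),
    }
    if band is not None:
        meta["band"] = band
    if date is not None:
        meta["date"] = date.isoformat() if isinstance(date, _dt.date) else str(date)
    if extra:
        meta.update(extra)
    tifffile.imwrite(path, np.asarray(array), description=json.dumps(meta))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a single-band raster and its JSON metadata.

    A declared integer ``scale``/``offset`` (e.g. Landsat surface
    reflectance stored as scaled integers) is applied so the returned
    array is floating point on the 0-1 reflectance scale; declared nodata
    values become NaN in float output.
    """
    with tifffile.TiffFile(path) as tif:
        array = tif.asarray()
        desc = tif.pages[0].description
    meta: dict[str, Any] = json.loads(desc) if desc else {}
    scale = meta.get("scale")
    offset = meta.get("offset", 0.0)
    nodata = meta.get("nodata")
    if scale is not None:
        out = array.astype(np.float64)
        if nodata is not None:
            out[array == nodata] = np.nan
        out = out * float(scale) + float(offset)
        return out, meta
    if np.issubdtype(array.dtype, np.floating) and nodata is not None:
        array = array.astype(np.float64)
        array[array == nodata] = np.nan
    return array, meta


def mask_to_polygons(
    mask: np.ndarray, pixel_size: float = 30.0, origin: tuple[float, float] = (0.0, 0.0)
):
    """Union of pixel squares for the True cells of a boolean mask.

    Row 0 is the northern edge; coordinates are (x east, y south-negative)
    in metres from ``origin``.
    """
    x0, y0 = origin
    cells = [
        box(
            x0 + c * pixel_size,
            y0 - (r + 1) * pixel_size,
            x0 + (c + 1) * pixel_size,
            y0 - r * pixel_size,
        )
        for r, c in zip(*np.nonzero(mask))
    ]
    return unary_union(cells)


def mask_to_geojson(
    path: str | Path,
    mask: np.ndarray,
    *,
    pixel_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
    properties: dict[str, Any] | None = None,
) -> Path:
    """Export a boolean mask's polygon outline as a GeoJSON feature."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    geom = mask_to_polygons(mask, pixel_size=pixel_size, origin=origin)
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": mapping(geom),
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    path.write_text(json.dumps(doc))
    return path


def write_config(path: str | Path, values: dict[str, Any]) -> Path:
    """Write a flat ``key = value`` text config, one entry per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for key, value in values.items():
        if isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat key-value config file; all values returned as strings."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
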