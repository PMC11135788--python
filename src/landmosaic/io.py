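"""GeoTIFF raster input/output.

Rasters are read and written with :mod:`tifffile`.  Values, dtype and the
nodata tag round-trip exactly; georeferencing (the GeoTIFF model/key tags
and GDAL metadata tags) is preserved verbatim and passed through every
product raster unchanged.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .raster import LandCoverRaster

__all__ = ["read_raster", "write_raster", "read_geotags", "write_array"]

# GeoTIFF + GDAL tags carried through unchanged
GEO_TAGS = (33550, 33922, 34264, 34735, 34736, 34737, 42112, 42113)

# TIFF DATATYPE enum value -> struct format char accepted by tifffile extratags
_DTYPE_CHAR = {
    1: "B", 2: "s", 3: "H", 4: "I", 5: "2I", 8: "h", 9: "i",
    11: "f", 12: "d", 16: "Q", 17: "q",
}


def read_geotags(page: "tifffile.TiffPage") -> dict[int, tuple[str, Any]]:
    tags: dict[int, tuple[str, Any]] = {}
    for code in GEO_TAGS:
        tag = page.tags.get(code)
        if tag is not None:
            char = _DTYPE_CHAR.get(int(tag.dtype), None)
            if char is not None:
                tags[code] = (char, tag.value)
    return tags


def _extratags(geotags: dict[int, tuple[str, Any]]) -> list[tuple]:
    out = []
    for code, (char, value) in sorted(geotags.items()):
        if char == "s":
            out.append((code, "s", 0, str(value), True))
        else:
            v = np.atleast_1d(np.asarray(value)).tolist()
            out.append((code, char, len(v), tuple(v), True))
    return out


def _pixel_size_from_tags(geotags: dict[int, tuple[str, Any]], default: float) -> float:
    scale = geotags.get(33550)
    if scale is not None:
        v = np.atleast_1d(np.asarray(scale[1], dtype=float))
        if v.size >= 1 and v[0] > 0:
            return float(v[0])
    return default


def read_grid(
    path: str | Path, pixel_size: float | None = None
) -> tuple[np.ndarray, float, dict[int, tuple[str, Any]]]:
    """Read any single-band integer GeoTIFF without dialect validation.

    Returns (grid, pixel_size, geotags); used for legend rasters that still
    need recoding.  The pixel size comes from the GeoTIFF pixel-scale tag
    when present (30 m otherwise) unless given explicitly.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        geotags = read_geotags(page)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: expected an integer band, got {data.dtype}")
    ps = pixel_size if pixel_size is not None else _pixel_size_from_tags(geotags, 30.0)
    return data, ps, geotags


def read_raster(path: str | Path, pixel_size: float | None = None) -> LandCoverRaster:
    """Read a single-band 8-bit land-cover GeoTIFF (codes 0–3, 0 = nodata)."""
    data, ps, geotags = read_grid(path, pixel_size)
    return LandCoverRaster(data, ps, geotags)


def write_raster(raster: LandCoverRaster, path: str | Path) -> None:
    """Write a land-cover raster as 8-bit GeoTIFF with nodata 0 tagged."""
    write_array(raster.data.astype(np.uint8), path, raster.geotags, nodata=0)


def write_array(
    data: np.ndarray,
    path: str | Path,
    geotags: dict[int, tuple[str, Any]] | None = None,
    nodata: int | float | None = None,
) -> None:
    """Write any 2-D integer array as single-band GeoTIFF, carrying the
    source's georeferencing tags and a GDAL nodata tag."""
    geotags = dict(geotags or {})
    if nodata is not None:
        geotags[42113] = ("s", str(int(nodata)))
    tifffile.imwrite(
        path,
        np.asarray(data),
        photometric="minisblack",
        extratags=_extratags(geotags),
    )
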