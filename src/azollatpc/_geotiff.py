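"""Minimal single-band GeoTIFF read/write built on tifffile.

Handles exactly what the pipeline needs: a float32 band, a north-up affine
transform (ModelPixelScale + ModelTiepoint tags), an EPSG code (GeoKey
directory) and a declared nodata sentinel (GDAL_NODATA tag).  Rotated or
sheared transforms are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GDAL_NODATA = 42113

GEOKEY_MODEL_TYPE = 1024
GEOKEY_RASTER_TYPE = 1025
GEOKEY_GEOGRAPHIC_CRS = 2048
GEOKEY_PROJECTED_CRS = 3072


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeferencing: pixel (row, col) -> world (x, y).

    ``x = x_origin + col * pixel_width``; ``y = y_origin - row * pixel_height``
    with the origin at the outer corner of the top-left pixel.
    """

    x_origin: float
    y_origin: float
    pixel_width: float
    pixel_height: float

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.pixel_width
        y = self.y_origin - (row + 0.5) * self.pixel_height
        return x, y


def _epsg_code(crs: str) -> int:
    crs = crs.strip().upper()
    if crs.startswith("EPSG:"):
        return int(crs.split(":", 1)[1])
    return int(crs)


def write_geotiff(
    path: str | Path,
    values: np.ndarray,
    transform: GridTransform,
    crs: str = "EPSG:4326",
    nodata: float = -9999.0,
) -> None:
    """Write a single-band float32 GeoTIFF with georeferencing tags."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {values.shape}")
    epsg = _epsg_code(crs)
    # geographic CRS codes live in 4000-4999; everything else we tag projected
    geographic = 4000 <= epsg <= 4999
    keys = [
        (GEOKEY_MODEL_TYPE, 0, 1, 2 if geographic else 1),
        (GEOKEY_RASTER_TYPE, 0, 1, 1),
        (
            GEOKEY_GEOGRAPHIC_CRS if geographic else GEOKEY_PROJECTED_CRS,
            0,
            1,
            epsg,
        ),
    ]
    directory = [1, 1, 0, len(keys)]
    for key in keys:
        directory.extend(key)
    extratags = [
        (
            TAG_MODEL_PIXEL_SCALE,
            "d",
            3,
            (transform.pixel_width, transform.pixel_height, 0.0),
            False,
        ),
        (
            TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, transform.x_origin, transform.y_origin, 0.0),
            False,
        ),
        (TAG_GEO_KEY_DIRECTORY, "H", len(directory), tuple(directory), False),
        (TAG_GDAL_NODATA, "s", 0, str(nodata), False),
    ]
    tifffile.imwrite(str(path), values, extratags=extratags)


def read_geotiff(path: str | Path):
    """Read a single-band GeoTIFF -> (values, GridTransform, crs, nodata)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float32)
        tags = {tag.code: tag.value for tag in page.tags.values()}
    if TAG_MODEL_PIXEL_SCALE not in tags or TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = tags[TAG_MODEL_PIXEL_SCALE][:2]
    tp = tags[TAG_MODEL_TIEPOINT]
    i, j, _, x, y, _ = tp[:6]
    transform = GridTransform(
        x_origin=float(x) - float(j) * float(sx),
        y_origin=float(y) + float(i) * float(sy),
        pixel_width=float(sx),
        pixel_height=float(sy),
    )
    crs = "EPSG:4326"
    directory = tags.get(TAG_GEO_KEY_DIRECTORY)
    if directory is not None:
        d = list(directory)
        n_keys = d[3]
        for k in range(n_keys):
            key_id, _, _, value = d[4 + 4 * k : 8 + 4 * k]
            if key_id in (GEOKEY_GEOGRAPHIC_CRS, GEOKEY_PROJECTED_CRS):
                crs = f"EPSG:{value}"
    nodata = -9999.0
    if TAG_GDAL_NODATA in tags:
        raw = tags[TAG_GDAL_NODATA]
        if isinstance(raw, bytes):
            raw = raw.decode("ascii", "ignore")
        nodata = float(str(raw).strip("\x00").strip())
    return values, transform, crs, nodata
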