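"""Single-band GeoTIFF reading and writing for north-up EPSG:4326 grids.

The pipeline's raster products are plain single-band float32 (or integer)
GeoTIFFs in geographic lat/lon (WGS84) with a -9999 nodata sentinel.
Files are written with ``tifffile`` plus the GeoTIFF georeferencing tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and the GDAL nodata
tag, which is all a north-up geographic grid needs; no general
affine/rotation support is attempted.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import tifffile

__all__ = ["GeoTransform", "NODATA", "write_geotiff", "read_geotiff"]

#: Default nodata sentinel for all raster products.
NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKeyDirectory: version 1.1.0, 3 keys — geographic model, pixel-is-area,
# geographic CRS EPSG:4326.
_GEOKEYS_WGS84 = (1, 1, 0, 3,
                  1024, 0, 1, 2,
                  1025, 0, 1, 1,
                  2048, 0, 1, 4326)


class GeoTransform(NamedTuple):
    """North-up georeference: upper-left corner and positive pixel sizes.

    ``west``/``north`` are the outer corner of the upper-left pixel in
    degrees; ``xres``/``yres`` the pixel width/height in degrees (both
    positive; rows run southward).
    """

    west: float
    north: float
    xres: float
    yres: float

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a pixel center."""
        return (self.west + (col + 0.5) * self.xres,
                self.north - (row + 0.5) * self.yres)


def write_geotiff(path, values: np.ndarray, transform: GeoTransform,
                  nodata: float = NODATA) -> None:
    """Write one 2-D band as an EPSG:4326 GeoTIFF.

    Float inputs are stored as float32 with NaN replaced by ``nodata``;
    integer inputs are stored as int32.  Output bytes are a pure function
    of the inputs (no timestamps), so identical grids give identical
    files.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("expected a single 2-D band")
    if np.issubdtype(values.dtype, np.floating):
        band = np.where(np.isfinite(values), values, nodata).astype(np.float32)
    else:
        band = values.astype(np.int32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (float(transform.xres), float(transform.yres), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(transform.west), float(transform.north), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, band, extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GeoTransform, float | None]:
    """Read a single-band GeoTIFF back as (band, transform, nodata).

    Float bands come back as float64 with nodata replaced by NaN.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        band = page.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        transform = GeoTransform(west=float(tie[3]), north=float(tie[4]),
                                 xres=float(scale[0]), yres=float(scale[1]))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    if np.issubdtype(band.dtype, np.floating):
        band = band.astype(float)
        if nodata is not None:
            band[band == nodata] = np.nan
    return band, transform, nodata
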