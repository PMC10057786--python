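"""Minimal georeferenced raster container with TIFF-backed IO.

A `Raster` is a 2-D (or band-stacked 3-D) float array plus the north-up
affine geotransform ``(x0, y0, pixel_size_x, pixel_size_y)`` — x0/y0 is the
outer corner of the top-left pixel and pixel_size_y is negative for the usual
row-down orientation — a CRS tag and a nodata convention (NaN in memory).
Files are plain TIFFs written with tifffile; the georeferencing travels as a
JSON payload in the image description so rasters round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["GridGeoref", "Raster"]


@dataclass(frozen=True)
class GridGeoref:
    """North-up affine georeferencing for a raster grid."""

    x0: float
    y0: float
    px: float   # pixel width (map units, > 0)
    py: float   # pixel height (map units, < 0 for row-down grids)

    def __post_init__(self) -> None:
        if self.px <= 0 or self.py >= 0:
            raise ValueError("expect px > 0 and py < 0 (north-up grid)")

    def world_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (row, col) of a map coordinate."""
        return (y - self.y0) / self.py, (x - self.x0) / self.px

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.px,
            self.y0 + (row + 0.5) * self.py,
        )


@dataclass
class Raster:
    """Array + georeferencing; nodata is NaN."""

    data: np.ndarray
    georef: GridGeoref
    crs: str = ""
    band_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or (bands, rows, cols) 3-D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[-2:]

    def band(self, name: str) -> np.ndarray:
        if self.data.ndim != 3 or name not in self.band_names:
            raise KeyError(f"no band named {name!r}")
        return self.data[self.band_names.index(name)]

    def write(self, path: str) -> None:
        meta = {
            "georef": [self.georef.x0, self.georef.y0, self.georef.px, self.georef.py],
            "crs": self.crs,
            "band_names": list(self.band_names),
        }
        tifffile.imwrite(path, self.data.astype(np.float32),
                         description=json.dumps(meta))

    @classmethod
    def read(cls, path: str) -> "Raster":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray().astype(float)
            desc = tif.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
            g = meta["georef"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise ValueError(f"{path}: missing georeferencing metadata") from exc
        return cls(
            data=data,
            georef=GridGeoref(*(float(v) for v in g)),
            crs=meta.get("crs", ""),
            band_names=tuple(meta.get("band_names", [])),
        )
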