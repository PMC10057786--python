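"""NBR time-series products and site-level geospatial covariates.

The normalised burn ratio, NBR = (NIR - SWIR2) / (NIR + SWIR2), is computed
per scene from surface reflectance; stacking the per-year NBR rasters gives a
pixelwise mean (vegetation cover and condition) and sample standard deviation
(variability over time — elevated where disturbance recurred). Site-level
covariates are the NBR mean/sd at the nearest pixel plus planar distances to
the river and drainage-canal networks.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

from .raster import GridGeoref, Raster

__all__ = [
    "SceneStack",
    "NbrProducts",
    "nbr",
    "stack_stats",
    "normality_check",
    "extract_at_sites",
    "distance_to_line",
    "read_geojson_lines",
    "write_geojson_lines",
    "site_covariates",
]


@dataclass
class SceneStack:
    """Co-registered multi-year NIR / SWIR-2 reflectance rasters.

    `nir` and `swir2` are (years, rows, cols) arrays of reflectance in [0, 1]
    with NaN nodata; every year shares the grid, georeferencing and CRS.
    """

    years: list[int]
    nir: np.ndarray
    swir2: np.ndarray
    georef: GridGeoref
    crs: str = ""

    def __post_init__(self) -> None:
        self.nir = np.atleast_3d(np.asarray(self.nir, dtype=float))
        self.swir2 = np.atleast_3d(np.asarray(self.swir2, dtype=float))
        if self.nir.shape != self.swir2.shape:
            raise ValueError("NIR and SWIR2 stacks differ in shape")
        if self.nir.shape[0] != len(self.years):
            raise ValueError("year list does not match stack depth")
        for name, band in (("nir", self.nir), ("swir2", self.swir2)):
            valid = band[np.isfinite(band)]
            if valid.size and (valid.min() < 0 or valid.max() > 1):
                raise ValueError(f"{name} reflectance outside [0, 1]")

    def write(self, out_dir: str) -> None:
        """Write one two-band (NIR, SWIR2) TIFF per year."""
        os.makedirs(out_dir, exist_ok=True)
        for i, year in enumerate(self.years):
            Raster(
                data=np.stack([self.nir[i], self.swir2[i]]),
                georef=self.georef, crs=self.crs, band_names=("nir", "swir2"),
            ).write(os.path.join(out_dir, f"scene_{year}.tif"))

    @classmethod
    def read(cls, scene_dir: str) -> "SceneStack":
        paths = sorted(
            p for p in os.listdir(scene_dir)
            if p.startswith("scene_") and p.endswith(".tif")
        )
        if not paths:
            raise FileNotFoundError(f"no scene_<year>.tif files in {scene_dir}")
        years, nir, swir2, georef, crs = [], [], [], None, ""
        for p in paths:
            r = Raster.read(os.path.join(scene_dir, p))
            years.append(int(p[len("scene_"):-len(".tif")]))
            nir.append(r.band("nir"))
            swir2.append(r.band("swir2"))
            georef, crs = r.georef, r.crs
        return cls(years=years, nir=np.stack(nir), swir2=np.stack(swir2),
                   georef=georef, crs=crs)


@dataclass
class NbrProducts:
    """Per-year NBR rasters plus the stack mean and sample sd."""

    years: list[int]
    nbr_per_year: np.ndarray   # (years, rows, cols), NaN nodata
    nbr_mean: np.ndarray
    nbr_sd: np.ndarray
    georef: GridGeoref
    crs: str = ""

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for i, year in enumerate(self.years):
            Raster(self.nbr_per_year[i], self.georef, self.crs).write(
                os.path.join(out_dir, f"nbr_{year}.tif"))
        Raster(self.nbr_mean, self.georef, self.crs).write(
            os.path.join(out_dir, "nbr_mean.tif"))
        Raster(self.nbr_sd, self.georef, self.crs).write(
            os.path.join(out_dir, "nbr_sd.tif"))


def nbr(nir, swir2):
    """Normalised burn ratio, (NIR - SWIR2) / (NIR + SWIR2), in [-1, 1].

    Accepts scalars or arrays; pixels where NIR + SWIR2 = 0 (or either band
    is nodata) come back NaN.
    """
    nir = np.asarray(nir, dtype=float)
    swir2 = np.asarray(swir2, dtype=float)
    denom = nir + swir2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - swir2) / denom, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def stack_stats(stack: SceneStack) -> NbrProducts:
    """NBR per year plus pixelwise mean and sample (n-1) sd over valid years.

    Nodata propagates per pixel-year; pixels with fewer than two valid years
    get a NaN sd.
    """
    if len(stack.years) == 0:
        raise ValueError("empty scene stack")
    per_year = nbr(stack.nir, stack.swir2)
    valid = np.isfinite(per_year)
    n_valid = valid.sum(axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(n_valid >= 1, np.nanmean(per_year, axis=0), np.nan)
        sd = np.full(mean.shape, np.nan)
        enough = n_valid >= 2
        if enough.any():
            sd_all = np.nanstd(per_year, axis=0, ddof=1)
            sd[enough] = sd_all[enough]
    return NbrProducts(years=list(stack.years), nbr_per_year=per_year,
                       nbr_mean=mean, nbr_sd=sd,
                       georef=stack.georef, crs=stack.crs)


def normality_check(stack: SceneStack, sample_size: int = 200, seed: int = 0) -> pd.DataFrame:
    """Shapiro–Wilk test of per-pixel NBR series on a random pixel sample.

    Returns one row per sampled pixel (row, col, W, p, undefined flag for
    constant series); the ``reject_05`` column marks p < 0.05. Series need at
    least 3 valid years to be testable.
    """
    per_year = nbr(stack.nir, stack.swir2)
    nrow, ncol = per_year.shape[1:]
    rng = np.random.default_rng(seed)
    k = min(sample_size, nrow * ncol)
    flat = rng.choice(nrow * ncol, size=k, replace=False)
    rows = []
    for idx in flat:
        r, c = divmod(int(idx), ncol)
        series = per_year[:, r, c]
        series = series[np.isfinite(series)]
        rec = {"row": r, "col": c, "n": series.size,
               "W": np.nan, "p": np.nan, "undefined": True, "reject_05": False}
        if series.size >= 3 and np.ptp(series) > 0:
            w, p = sps.shapiro(series)
            rec.update(W=float(w), p=float(p), undefined=False,
                       reject_05=bool(p < 0.05))
        rows.append(rec)
    return pd.DataFrame(rows)


def extract_at_sites(
    raster: np.ndarray, georef: GridGeoref, sites: pd.DataFrame
) -> np.ndarray:
    """Nearest-pixel raster value for each site (no interpolation).

    `sites` needs `site_id`, `x`, `y` columns in the raster's CRS. A site
    outside the raster bounds raises an error naming the site.
    """
    raster = np.asarray(raster, dtype=float)
    nrow, ncol = raster.shape
    out = np.empty(len(sites))
    for i, (_, s) in enumerate(sites.iterrows()):
        fr, fc = georef.world_to_pixel(float(s["x"]), float(s["y"]))
        r, c = int(np.floor(fr)), int(np.floor(fc))
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError(f"site {s['site_id']!r} falls outside the raster bounds")
        out[i] = raster[r, c]
    return out


def distance_to_line(site_xy: tuple[float, float], lines: BaseGeometry, crs: str = "") -> float:
    """Minimum planar distance (m) from a point to a polyline set.

    Requires a projected CRS; a geographic (degree) CRS is rejected because
    planar distances in degrees are meaningless.
    """
    if crs and ("4326" in crs or "CRS84" in crs.upper() or "longlat" in crs):
        raise ValueError(
            f"CRS {crs!r} is geographic; project sites and lines to a metric CRS first"
        )
    if lines.is_empty:
        raise ValueError("empty polyline set")
    return float(Point(site_xy).distance(lines))


def read_geojson_lines(path: str) -> BaseGeometry:
    """Union of all (Multi)LineString geometries in a GeoJSON file."""
    from shapely.ops import unary_union

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    geoms = [shape(f["geometry"] if "geometry" in f else f) for f in feats]
    return unary_union(geoms)


def write_geojson_lines(geoms: list[BaseGeometry], path: str, crs: str = "") -> None:
    from shapely.geometry import mapping

    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(g)}
            for g in geoms
        ],
    }
    if crs:
        fc["crs"] = {"type": "name", "properties": {"name": crs}}
    with open(path, "w") as fh:
        json.dump(fc, fh)


def site_covariates(
    products: NbrProducts,
    sites: pd.DataFrame,
    river: BaseGeometry | None = None,
    canals: BaseGeometry | None = None,
) -> pd.DataFrame:
    """Join NBR stack statistics and line distances onto the site table."""
    out = sites[["site_id", "x", "y"]].copy()
    out["nbr_mean"] = extract_at_sites(products.nbr_mean, products.georef, sites)
    out["nbr_sd"] = extract_at_sites(products.nbr_sd, products.georef, sites)
    for name, geom in (("dist_river_m", river), ("dist_canal_m", canals)):
        if geom is None:
            out[name] = np.nan
        else:
            out[name] = [
                distance_to_line((x, y), geom, products.crs)
                for x, y in zip(out["x"], out["y"])
            ]
    return out
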