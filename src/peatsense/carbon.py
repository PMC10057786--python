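"""Bulk density, carbon density and carbon stocks for peat cores.

Each core is a contiguous column of 10 cm increments sampled with a
half-cylinder corer. Bulk density (oven-dry mass over chamber volume) times
the TOC fraction times the increment thickness gives a per-segment carbon
density in g cm^-2; summing down the profile and scaling by 100 converts to
the Mg ha^-1 stocks reported for peat. Vegetation carbon applies the 0.47
carbon-content factor to above-ground biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rockeval import classify_depth_layer

__all__ = [
    "DEFAULT_SEGMENT_VOLUME_CM3",
    "AGB_CARBON_FACTOR",
    "G_CM2_TO_MG_HA",
    "CoreSegment",
    "CoreStock",
    "half_cylinder_volume",
    "bulk_density",
    "segment_carbon_density",
    "vegetation_stock",
    "interpolate_toc",
    "core_stock",
    "stocks_from_tables",
]

#: Chamber volume of one 10 cm increment of a half-cylinder corer, r = 2.5 cm.
DEFAULT_SEGMENT_VOLUME_CM3 = 98.17

#: Carbon content fraction applied to above-ground biomass.
AGB_CARBON_FACTOR = 0.47

# Unit chain, documented once: 1 g cm^-2 = 1e4 g m^-2 = 1e8 g ha^-1
#                            = 1e2 Mg ha^-1.
G_CM2_TO_MG_HA = 100.0


def half_cylinder_volume(radius_cm: float, length_cm: float) -> float:
    """Volume (cm^3) of a half-cylinder corer chamber: pi r^2 L / 2."""
    if radius_cm <= 0 or length_cm <= 0:
        raise ValueError("radius and length must be positive")
    return math.pi * radius_cm**2 * length_cm / 2.0


def bulk_density(dry_g: float, volume_cm3: float = DEFAULT_SEGMENT_VOLUME_CM3) -> float:
    """Oven-dry mass over fresh sample volume, g cm^-3."""
    if volume_cm3 <= 0:
        raise ValueError("sample volume must be positive")
    if dry_g < 0:
        raise ValueError("dry mass cannot be negative")
    return dry_g / volume_cm3


def segment_carbon_density(bd_g_cm3: float, toc_wt_pct: float, thickness_cm: float = 10.0) -> float:
    """Carbon density of one increment, g cm^-2: bd * (TOC/100) * thickness."""
    if bd_g_cm3 < 0 or thickness_cm < 0:
        raise ValueError("bulk density and thickness must be non-negative")
    if not 0 <= toc_wt_pct <= 100:
        raise ValueError(f"TOC must be a weight percent in [0, 100], got {toc_wt_pct}")
    return bd_g_cm3 * (toc_wt_pct / 100.0) * thickness_cm


def vegetation_stock(agb_mg_ha: float, factor: float = AGB_CARBON_FACTOR) -> float:
    """Carbon stock (Mg ha^-1) in above-ground biomass: factor * AGB."""
    if agb_mg_ha < 0:
        raise ValueError("AGB cannot be negative")
    return factor * agb_mg_ha


@dataclass
class CoreSegment:
    """One 10 cm increment of a peat core."""

    top_cm: float
    bottom_cm: float
    wet_g: float
    dry_g: float
    volume_cm3: float = DEFAULT_SEGMENT_VOLUME_CM3
    toc_wt_pct: float | None = None  # None where Rock-Eval was not run
    layer: str = ""

    def __post_init__(self) -> None:
        if self.bottom_cm <= self.top_cm:
            raise ValueError(f"inverted segment ({self.top_cm}, {self.bottom_cm})")
        if self.dry_g > self.wet_g:
            raise ValueError("dry mass exceeds wet mass")

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm

    @property
    def mid_cm(self) -> float:
        return 0.5 * (self.top_cm + self.bottom_cm)

    @property
    def bulk_density_g_cm3(self) -> float:
        return bulk_density(self.dry_g, self.volume_cm3)


@dataclass(frozen=True)
class CoreStock:
    """Carbon stocks for one core / site (Mg ha^-1)."""

    site_id: str
    condition_class: str
    peat_stock_mg_ha: float
    upper50_stock_mg_ha: float
    veg_stock_mg_ha: float
    peat_depth_m: float

    def __post_init__(self) -> None:
        if min(self.peat_stock_mg_ha, self.upper50_stock_mg_ha, self.veg_stock_mg_ha) < 0:
            raise ValueError("stocks cannot be negative")
        if self.upper50_stock_mg_ha > self.peat_stock_mg_ha + 1e-9:
            raise ValueError("upper-50 cm stock exceeds whole-profile stock")


def interpolate_toc(segments: list[CoreSegment]) -> np.ndarray:
    """Fill unmeasured segment TOC by linear depth-interpolation.

    Rock-Eval is typically run on selected sub-samples only; segments without
    a measurement take the TOC linearly interpolated (by segment midpoint
    depth) between measured neighbours, constant-extrapolated at core ends.
    """
    mids = np.array([s.mid_cm for s in segments])
    toc = np.array([np.nan if s.toc_wt_pct is None else s.toc_wt_pct for s in segments])
    measured = ~np.isnan(toc)
    if not measured.any():
        raise ValueError("core has no measured TOC; cannot compute carbon stock")
    return np.interp(mids, mids[measured], toc[measured])


def core_stock(
    segments: list[CoreSegment],
    site_id: str = "",
    condition_class: str = "",
    agb_mg_ha: float = 0.0,
) -> CoreStock:
    """Sum per-segment carbon densities into whole-profile and upper-50 stocks.

    Segments must form a contiguous column from the surface; the whole-profile
    stock sums every increment (g cm^-2, converted to Mg ha^-1); the upper-50
    stock is restricted to segments whose bottom lies within the top 50 cm.
    """
    if not segments:
        raise ValueError("no segments")
    segs = sorted(segments, key=lambda s: s.top_cm)
    tops = np.array([s.top_cm for s in segs])
    bottoms = np.array([s.bottom_cm for s in segs])
    if tops[0] != 0 or np.any(np.abs(tops[1:] - bottoms[:-1]) > 1e-9):
        raise ValueError("segments must be contiguous from the surface")
    toc = interpolate_toc(segs)
    dens = np.array([
        segment_carbon_density(s.bulk_density_g_cm3, t, s.thickness_cm)
        for s, t in zip(segs, toc)
    ])
    upper = np.array([s.bottom_cm <= 50.0 for s in segs])
    return CoreStock(
        site_id=site_id,
        condition_class=condition_class,
        peat_stock_mg_ha=float(dens.sum()) * G_CM2_TO_MG_HA,
        upper50_stock_mg_ha=float(dens[upper].sum()) * G_CM2_TO_MG_HA,
        veg_stock_mg_ha=vegetation_stock(agb_mg_ha),
        peat_depth_m=float(bottoms[-1]) / 100.0,
    )


def stocks_from_tables(
    cores: pd.DataFrame,
    rockeval: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    volume_cm3: float = DEFAULT_SEGMENT_VOLUME_CM3,
) -> pd.DataFrame:
    """Compute per-core stocks from the tabular interfaces.

    `cores` has one row per segment (site_id, class, segment_top_cm,
    segment_bottom_cm, wet_g, dry_g); `rockeval` carries sample_id of the form
    ``<site_id>_<top_cm>`` plus TOC; `sites` optionally supplies agb_mg_ha.
    """
    toc_map = {}
    for _, r in rockeval.iterrows():
        sid = str(r["sample_id"])
        if sid.endswith("_litter"):
            continue
        site, top = sid.rsplit("_", 1)
        toc_map[(site, float(top))] = float(r["TOC"])
    agb_map = {}
    if sites is not None and "agb_mg_ha" in sites.columns:
        agb_map = dict(zip(sites["site_id"].astype(str), sites["agb_mg_ha"]))
    out = []
    for (site, cls), grp in cores.groupby(["site_id", "class"], sort=True):
        segs = [
            CoreSegment(
                top_cm=row["segment_top_cm"], bottom_cm=row["segment_bottom_cm"],
                wet_g=row["wet_g"], dry_g=row["dry_g"], volume_cm3=volume_cm3,
                toc_wt_pct=toc_map.get((str(site), float(row["segment_top_cm"]))),
            )
            for _, row in grp.iterrows()
        ]
        st = core_stock(segs, site_id=str(site), condition_class=str(cls),
                        agb_mg_ha=float(agb_map.get(str(site), 0.0)))
        out.append({
            "site_id": st.site_id, "class": st.condition_class,
            "peat_stock_mg_ha": st.peat_stock_mg_ha,
            "upper50_stock_mg_ha": st.upper50_stock_mg_ha,
            "veg_stock_mg_ha": st.veg_stock_mg_ha,
            "peat_depth_m": st.peat_depth_m,
        })
    return pd.DataFrame(out)


def label_layers(
    cores: pd.DataFrame, water_table_cm: float = 40.0
) -> pd.DataFrame:
    """Attach the depth-stratum label to every segment row of `cores`.

    The clay contact is taken as the bottom of each core's deepest segment.
    """
    cores = cores.copy()
    clay = cores.groupby("site_id")["segment_bottom_cm"].transform("max")
    cores["layer"] = [
        classify_depth_layer(t, b, water_table_cm, c)
        for t, b, c in zip(cores["segment_top_cm"], cores["segment_bottom_cm"], clay)
    ]
    return cores
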