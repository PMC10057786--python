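"""Synthetic peat-core, pyrogram and reflectance-stack generator.

Builds study-shaped datasets with the structure the downstream analysis
assumes: pristine cores whose organic matter matures with depth (labile pools
shrinking, refractory pools growing, so the I-index falls and the R-index
rises), disturbed cores whose upper 50 cm is additionally thermally
stabilised (labile mass depleted, mimicking oxidation and fire), and
multi-year NIR/SWIR-2 reflectance stacks whose NBR is lower and more variable
over time above disturbed sites. Everything is driven by one seeded
generator, so a fixed seed reproduces every file byte for byte.

The S2 pyrogram of each sample is a mixture of four Gaussian components
standing for the organic-matter pools behind the A1–A4 temperature nodes:
labile fresh plant matter, lignin/cellulose, humified macromolecules, and
recalcitrant/char material.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely.geometry import LineString

from .raster import GridGeoref
from .remote_sensing import SceneStack, write_geojson_lines
from .rockeval import Pyrogram, write_pyrogram_csv

__all__ = [
    "CONDITION_CLASSES",
    "ThermalComponent",
    "SiteScenario",
    "TempProgram",
    "StudyConfig",
    "PeatCore",
    "StudyDataset",
    "default_composition",
    "generate_pyrogram",
    "generate_core",
    "generate_study",
]

CONDITION_CLASSES = (
    "CentralForest", "ManagedRecovery", "DisturbedForest", "FireAffected",
)


@dataclass(frozen=True)
class ThermalComponent:
    """One organic-matter pool: a Gaussian peak in the S2 pyrogram."""

    center_temp: float    # °C
    width: float          # °C, Gaussian sigma
    mass_fraction: float  # unitless, in [0, 1]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("component width must be positive")
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError("mass fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TempProgram:
    """Instrument temperature program for both analysis phases."""

    hold_temp_c: float = 200.0
    hold_min: float = 3.0
    ramp_end_c: float = 650.0
    ramp_rate_c_min: float = 25.0
    step_c: float = 1.0
    oxid_start_c: float = 300.0
    oxid_end_c: float = 850.0
    oxid_rate_c_min: float = 20.0

    def ramp_grid(self) -> np.ndarray:
        return np.arange(self.hold_temp_c, self.ramp_end_c + self.step_c / 2, self.step_c)

    def oxidation_grid(self) -> np.ndarray:
        return np.arange(self.oxid_start_c, self.oxid_end_c + self.step_c / 2, self.step_c)


@dataclass(frozen=True)
class SiteScenario:
    """Condition-class scenario for one core / site."""

    condition_class: str = "CentralForest"
    peat_depth: float = 2.5            # m
    water_table_depth: float = 0.4     # m below surface (dry season)
    upper_labile_depletion: float = 0.0  # in [0, 1]; 0 for pristine
    nbr_baseline: float = 0.55
    nbr_temporal_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition_class not in CONDITION_CLASSES:
            raise ValueError(f"unknown condition class {self.condition_class!r}")
        if self.peat_depth <= 0:
            raise ValueError("peat depth must be positive")
        if not 0.0 <= self.upper_labile_depletion <= 1.0:
            raise ValueError("upper_labile_depletion must lie in [0, 1]")
        if not -1.0 <= self.nbr_baseline <= 1.0:
            raise ValueError("nbr_baseline must lie in [-1, 1]")


# Per-class defaults: labile depletion of the upper 50 cm, NBR level and
# temporal sd of the surrounding pixels, mean above-ground biomass (Mg/ha).
CLASS_DEFAULTS: dict[str, dict] = {
    "CentralForest":   {"upper_labile_depletion": 0.00, "nbr_baseline": 0.55,
                        "nbr_temporal_sd": 0.03, "agb_mean": 280.0},
    "ManagedRecovery": {"upper_labile_depletion": 0.35, "nbr_baseline": 0.40,
                        "nbr_temporal_sd": 0.08, "agb_mean": 180.0},
    "DisturbedForest": {"upper_labile_depletion": 0.30, "nbr_baseline": 0.35,
                        "nbr_temporal_sd": 0.10, "agb_mean": 120.0},
    "FireAffected":    {"upper_labile_depletion": 0.45, "nbr_baseline": 0.25,
                        "nbr_temporal_sd": 0.13, "agb_mean": 60.0},
}

#: Default component centers/sigmas: mid-window placements for A1–A3 and a
#: representative >460 °C center for the char pool.
COMPONENT_CENTERS = (310.0, 370.0, 430.0, 500.0)
COMPONENT_SIGMAS = (15.0, 15.0, 15.0, 20.0)


def default_composition(fractions) -> list[ThermalComponent]:
    """Four-pool composition at the default centers with given fractions."""
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 4:
        raise ValueError("expected four mass fractions")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions must sum to 1, got {fr.sum()!r}")
    return [
        ThermalComponent(c, s, float(f))
        for c, s, f in zip(COMPONENT_CENTERS, COMPONENT_SIGMAS, fr)
    ]


def generate_pyrogram(
    composition: list[ThermalComponent],
    total_s2: float,
    temp_program: TempProgram | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    s1: float = 0.0,
    s3_co: float = 0.0,
    s3_co2: float = 0.0,
    sample_id: str = "",
) -> Pyrogram:
    """Synthesise a two-stage pyrogram from a thermal-pool composition.

    The ramp-phase FID curve is a truncation-normalised Gaussian mixture whose
    trapezoid area over the ramp equals `total_s2` exactly at noise 0. The
    optional hold phase carries `s1` as a time-indexed release curve, and the
    oxidation phase carries single-Gaussian CO / CO2 curves with masses
    `s3_co` / `s3_co2` (shape is illustrative only — it exists to exercise the
    TOC / OI assembly, not to model oxidation chemistry).
    """
    prog = temp_program or TempProgram()
    if not composition:
        raise ValueError("composition is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lo, hi = prog.hold_temp_c, prog.ramp_end_c
    for comp in composition:
        if not lo <= comp.center_temp <= hi:
            raise ValueError(
                f"component center {comp.center_temp} outside the ramp [{lo}, {hi}]"
            )
    fractions = sum(c.mass_fraction for c in composition)
    if abs(fractions - 1.0) > 1e-9:
        raise ValueError(f"mass fractions must sum to 1, got {fractions!r}")

    rng = np.random.default_rng(seed)
    temps = prog.ramp_grid()
    fid = np.zeros_like(temps)
    for comp in composition:
        # normalise by the truncated mass so the in-window area is exact
        trunc = norm.cdf(hi, comp.center_temp, comp.width) - norm.cdf(
            lo, comp.center_temp, comp.width)
        fid += (total_s2 * comp.mass_fraction / trunc) * norm.pdf(
            temps, comp.center_temp, comp.width)
    if noise_sd > 0:
        fid = fid + rng.normal(0.0, noise_sd, size=fid.shape)

    hold_t = hold_fid = np.array([])
    if s1 > 0:
        hold_t = np.arange(0.0, prog.hold_min + 1e-9, 0.05)
        shape = hold_t * np.exp(-2.0 * hold_t)
        hold_fid = s1 * shape / np.trapezoid(shape, hold_t)

    oxid_t = prog.oxidation_grid()
    co = np.zeros_like(oxid_t)
    co2 = np.zeros_like(oxid_t)
    for mass, center, sigma, target in ((s3_co, 450.0, 60.0, "co"),
                                        (s3_co2, 520.0, 85.0, "co2")):
        if mass > 0:
            trunc = norm.cdf(oxid_t[-1], center, sigma) - norm.cdf(oxid_t[0], center, sigma)
            curve = (mass / trunc) * norm.pdf(oxid_t, center, sigma)
            if target == "co":
                co = curve
            else:
                co2 = curve
    return Pyrogram(
        pyrolysis_temps=temps, fid_signal=fid,
        oxidation_temps=oxid_t, co_signal=co, co2_signal=co2,
        hold_times_min=hold_t, hold_fid=hold_fid, sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# cores


@dataclass
class CoreSample:
    """One measured sub-sample: its pyrogram plus its depth label."""

    sample_id: str
    top_cm: float | None      # None for litter
    pyrogram: Pyrogram


@dataclass
class PeatCore:
    """One simulated core: 10 cm increments plus measured pyrograms."""

    site_id: str
    condition_class: str
    water_table_cm: float
    segments: pd.DataFrame           # top_cm, bottom_cm, wet_g, dry_g
    samples: list[CoreSample]        # measured sub-samples incl. litter

    @property
    def clay_top_cm(self) -> float:
        return float(self.segments["bottom_cm"].max())


def _depth_fractions(mid_cm: float) -> np.ndarray:
    """Four-pool mass fractions at a given depth for an undisturbed profile.

    Calibrated so a pristine profile spans roughly R 0.50 -> 0.64 and
    I 0.19 -> 0.0 from surface to 3.5 m, the decomposition trend expected of
    an intact ombrotrophic peat column.
    """
    t = min(max(mid_cm, 0.0), 350.0) / 350.0
    f = np.array([
        0.26 - 0.08 * t,   # labile fresh plant matter
        0.22 - 0.03 * t,   # lignin / cellulose
        0.32 + 0.04 * t,   # humified macromolecules
        0.20 + 0.07 * t,   # recalcitrant / char
    ])
    return f / f.sum()


LITTER_FRACTIONS = np.array([0.50, 0.27, 0.14, 0.09])


def generate_core(scenario: SiteScenario, site_id: str = "core") -> PeatCore:
    """Simulate one peat core under a condition-class scenario.

    Increment dry masses centre bulk density on 0.10 g/cm3; compositions
    mature with depth, and for disturbed scenarios the labile pools of the
    upper 50 cm are multiplied by (1 - upper_labile_depletion) before
    renormalisation — pushing the R-index up and the I-index down exactly
    where surface degradation acts. Rock-Eval sub-samples are taken on
    alternating increments (plus the deepest one) and a litter sample is
    always included.
    """
    rng = np.random.default_rng(scenario.seed)
    n_seg = int(round(scenario.peat_depth * 10.0))
    if n_seg < 1:
        raise ValueError("peat depth too small for a single 10 cm increment")

    tops = 10.0 * np.arange(n_seg)
    bd = np.clip(rng.normal(0.10, 0.008, n_seg), 0.06, 0.14)
    dry = bd * 98.17
    dry_frac = np.clip(rng.normal(0.12, 0.01, n_seg), 0.08, 0.20)
    wet = dry / dry_frac

    segments = pd.DataFrame({
        "top_cm": tops, "bottom_cm": tops + 10.0,
        "wet_g": wet, "dry_g": dry,
    })

    measured = sorted(set(range(0, n_seg, 2)) | {n_seg - 1})
    samples: list[CoreSample] = []
    for idx in measured:
        top = tops[idx]
        mid = top + 5.0
        f = _depth_fractions(mid) + rng.normal(0.0, 0.012, 4)
        f = np.clip(f, 0.02, None)
        depletion = scenario.upper_labile_depletion if top + 10.0 <= 50.0 else 0.0
        f[:2] *= 1.0 - depletion
        f = f / f.sum()

        toc_target = float(np.clip(rng.normal(55.0, 2.0), 45.0, 65.0))
        hi_target = float(np.clip(rng.normal(430.0 - 80.0 * min(mid, 350.0) / 350.0, 15.0),
                                  150.0, 500.0))
        # degraded surface peat is dehydrogenated and carbon-depleted
        hi_target *= 1.0 - 0.35 * depletion
        toc_target *= 1.0 - 0.35 * depletion
        s2 = hi_target * toc_target / 100.0
        s1 = float(2.0 + 0.5 * rng.random())
        s3_co = 30.0
        co2 = (toc_target - 0.083 * (s1 + s2) - s3_co * 12.0 / 280.0) * 440.0 / 12.0
        s3_co2 = max(co2, 0.0)

        sid = f"{site_id}_{int(top)}"
        samples.append(CoreSample(
            sample_id=sid, top_cm=float(top),
            pyrogram=generate_pyrogram(
                default_composition(f), total_s2=s2,
                noise_sd=0.02 * s2 / 450.0, seed=int(rng.integers(2**31)),
                s1=s1, s3_co=s3_co, s3_co2=s3_co2, sample_id=sid,
            ),
        ))

    # leaf litter: labile-dominated, high HI, shallow decomposition state
    litter_toc = float(np.clip(rng.normal(50.0, 2.0), 40.0, 60.0))
    litter_s2 = 4.7 * litter_toc
    lit_id = f"{site_id}_litter"
    samples.append(CoreSample(
        sample_id=lit_id, top_cm=None,
        pyrogram=generate_pyrogram(
            default_composition(LITTER_FRACTIONS / LITTER_FRACTIONS.sum()),
            total_s2=litter_s2, noise_sd=0.02 * litter_s2 / 450.0,
            seed=int(rng.integers(2**31)),
            s1=3.0, s3_co=30.0,
            s3_co2=max((litter_toc - 0.083 * (3.0 + litter_s2)
                        - 30.0 * 12.0 / 280.0) * 440.0 / 12.0, 0.0),
            sample_id=lit_id,
        ),
    ))

    return PeatCore(
        site_id=site_id, condition_class=scenario.condition_class,
        water_table_cm=scenario.water_table_depth * 100.0,
        segments=segments, samples=samples,
    )


# ---------------------------------------------------------------------------
# full study


@dataclass(frozen=True)
class StudyConfig:
    """Study-level layout: sites per class, years, raster geometry.

    `class_contrast` scales every between-class difference (labile depletion,
    NBR level and temporal sd, biomass) relative to the CentralForest
    defaults; 1 is the full disturbance structure, 0 removes all class
    signal, giving a null dataset for calibration runs.
    """

    site_counts: dict = field(default_factory=lambda: {
        "CentralForest": 3, "ManagedRecovery": 2,
        "DisturbedForest": 4, "FireAffected": 2,
    })
    years: tuple[int, ...] = (1989, 1995, 2001, 2010, 2019)
    grid_shape: tuple[int, int] = (60, 60)
    origin: tuple[float, float] = (400000.0, 380000.0)
    pixel_size_m: float = 30.0
    crs: str = "EPSG:32647"
    depth_range_m: tuple[float, float] = (1.0, 3.5)
    water_table_m: float = 0.4
    class_contrast: float = 1.0
    seed: int = 0


@dataclass
class StudyDataset:
    """Everything one simulated campaign produces."""

    cores: list[PeatCore]
    stack: SceneStack
    river: LineString
    canals: list[LineString]
    sites: pd.DataFrame      # site_id, class, x, y, agb_mg_ha
    config: StudyConfig

    def cores_table(self) -> pd.DataFrame:
        rows = []
        for core in self.cores:
            seg = core.segments.copy()
            rows.append(pd.DataFrame({
                "site_id": core.site_id, "class": core.condition_class,
                "segment_top_cm": seg["top_cm"],
                "segment_bottom_cm": seg["bottom_cm"],
                "wet_g": seg["wet_g"], "dry_g": seg["dry_g"],
            }))
        return pd.concat(rows, ignore_index=True)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.cores_table().to_csv(os.path.join(out_dir, "cores.csv"), index=False)
        self.sites.to_csv(os.path.join(out_dir, "sites.csv"), index=False)
        pyro_dir = os.path.join(out_dir, "pyrograms")
        os.makedirs(pyro_dir, exist_ok=True)
        for core in self.cores:
            for s in core.samples:
                write_pyrogram_csv(s.pyrogram, os.path.join(pyro_dir, f"{s.sample_id}.csv"))
        self.stack.write(os.path.join(out_dir, "scenes"))
        write_geojson_lines([self.river], os.path.join(out_dir, "river.geojson"),
                            crs=self.config.crs)
        write_geojson_lines(self.canals, os.path.join(out_dir, "canals.geojson"),
                            crs=self.config.crs)


def _blend(cls_params: dict, contrast: float) -> dict:
    """Pull class parameters toward the CentralForest values by 1 - contrast."""
    base = CLASS_DEFAULTS["CentralForest"]
    return {k: base[k] + contrast * (cls_params[k] - base[k]) for k in base}


def generate_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyDataset:
    """Simulate a whole campaign: cores, reflectance stack, lines, biomass.

    Sites sit on a jittered grid inside the raster extent (one pixel each —
    coinciding site pixels are rejected); pixels in a disc around each site
    carry that class's NBR level and year-to-year variability, so the stack
    statistics downstream see lower, noisier NBR over disturbed ground.
    """
    cfg = config or StudyConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    n_sites = int(sum(cfg.site_counts.values()))
    if n_sites < 1:
        raise ValueError("need at least one site")
    if len(cfg.years) < 2:
        raise ValueError("need at least two years for a temporal sd")

    nrow, ncol = cfg.grid_shape
    georef = GridGeoref(cfg.origin[0], cfg.origin[1] + nrow * cfg.pixel_size_m,
                        cfg.pixel_size_m, -cfg.pixel_size_m)

    # jittered grid of site pixels, margin away from the edges
    n_gx = int(np.ceil(np.sqrt(n_sites)))
    n_gy = int(np.ceil(n_sites / n_gx))
    margin = 6
    gx = np.linspace(margin, ncol - margin, n_gx)
    gy = np.linspace(margin, nrow - margin, n_gy)
    cells = [(r, c) for r in gy for c in gx][:n_sites]
    pixels = []
    for r, c in cells:
        pr = int(round(r + rng.uniform(-2, 2)))
        pc = int(round(c + rng.uniform(-2, 2)))
        pixels.append((pr, pc))
    if len(set(pixels)) != len(pixels):
        raise ValueError("site coordinates overlap; choose a larger extent")

    class_list = [
        cls for cls in CONDITION_CLASSES for _ in range(int(cfg.site_counts.get(cls, 0)))
    ]

    # cores + site table
    cores, site_rows = [], []
    for i, (cls, (pr, pc)) in enumerate(zip(class_list, pixels)):
        params = _blend(CLASS_DEFAULTS[cls], cfg.class_contrast)
        depth = float(rng.uniform(*cfg.depth_range_m))
        scenario = SiteScenario(
            condition_class=cls, peat_depth=depth,
            water_table_depth=cfg.water_table_m,
            upper_labile_depletion=float(np.clip(params["upper_labile_depletion"], 0, 1)),
            nbr_baseline=params["nbr_baseline"],
            nbr_temporal_sd=params["nbr_temporal_sd"],
            seed=int(rng.integers(2**31)),
        )
        site_id = f"P{i + 1:02d}"
        cores.append(generate_core(scenario, site_id=site_id))
        x, y = georef.pixel_center(pr, pc)
        site_rows.append({
            "site_id": site_id, "class": cls, "x": x, "y": y,
            "agb_mg_ha": float(max(rng.normal(params["agb_mean"], 15.0), 5.0)),
            "_pr": pr, "_pc": pc,
            "_nbr_baseline": params["nbr_baseline"],
            "_nbr_sd": params["nbr_temporal_sd"],
        })
    sites = pd.DataFrame(site_rows)

    # reflectance stack: smooth background + per-site discs
    n_years = len(cfg.years)
    bg = 0.45 + 0.03 * rng.standard_normal((nrow, ncol))
    nbr_true = np.repeat(bg[None], n_years, axis=0)
    nbr_true = nbr_true + 0.02 * rng.standard_normal((n_years, nrow, ncol))
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    for _, s in sites.iterrows():
        disc = (rr - s["_pr"]) ** 2 + (cc - s["_pc"]) ** 2 <= 3.0**2
        yearly = rng.normal(s["_nbr_baseline"], s["_nbr_sd"], n_years)
        for t in range(n_years):
            nbr_true[t][disc] = yearly[t] + 0.01 * rng.standard_normal(int(disc.sum()))
    nbr_true = np.clip(nbr_true, -0.95, 0.95)
    total = 0.5  # NIR + SWIR2 reflectance budget
    nir = total * (1.0 + nbr_true) / 2.0
    swir2 = total - nir
    stack = SceneStack(years=list(cfg.years), nir=nir, swir2=swir2,
                       georef=georef, crs=cfg.crs)

    # river down the middle of the extent; canals through the disturbed half
    x0, y0 = cfg.origin
    w = ncol * cfg.pixel_size_m
    h = nrow * cfg.pixel_size_m
    xs = np.linspace(x0, x0 + w, 9)
    river = LineString([
        (x0 + w / 2 + 0.05 * w * np.sin(2 * np.pi * k / 8), y0 + h * k / 8)
        for k in range(9)
    ])
    disturbed = sites[sites["class"].isin(("DisturbedForest", "FireAffected"))]
    canals = []
    for _, s in disturbed.iterrows():
        yline = s["y"] + 2.5 * cfg.pixel_size_m
        canals.append(LineString([(xs[0], yline), (xs[-1], yline)]))
    if not canals:
        canals.append(LineString([(x0, y0 + h / 4), (x0 + w, y0 + h / 4)]))

    sites = sites.drop(columns=["_pr", "_pc", "_nbr_baseline", "_nbr_sd"])
    return StudyDataset(cores=cores, stack=stack, river=river, canals=canals,
                        sites=sites, config=cfg)
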