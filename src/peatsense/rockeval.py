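"""Rock-Eval 6 parameters and Sebag thermal-stability indices from pyrograms.

Rock-Eval 6 runs a two-stage thermal analysis: an inert-atmosphere pyrolysis
(hold at 200 °C, then ramp to 650 °C at 25 °C/min, hydrocarbons detected by
FID) followed by oxidation of the residual carbon (300–850 °C at 20 °C/min,
CO and CO2 detected by infrared). This module integrates those curves into
the standard parameters (S1, S2, S3 CO, S3 CO2, TOC, TpkS2, HI, OI), splits
the S2 pyrogram into the four Sebag temperature nodes A1–A4, and computes the
refractory (R) and immature (I) organic-matter indices that together track
the decomposition state of peat.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "A_WINDOWS",
    "Pyrogram",
    "NodeAreas",
    "TocFactors",
    "RockEvalResult",
    "UndefinedIndexError",
    "integrate_s2_nodes",
    "r_index",
    "i_index",
    "compute_parameters",
    "classify_depth_layer",
    "result_from_parameters",
    "read_pyrogram_csv",
    "write_pyrogram_csv",
    "process_directory",
]

#: Sebag S2 temperature windows (°C), half-open [lo, hi); A4 is open-ended.
A_WINDOWS = {
    "A1": (200.0, 340.0),
    "A2": (340.0, 400.0),
    "A3": (400.0, 460.0),
    "A4": (460.0, np.inf),
}


class UndefinedIndexError(ValueError):
    """Raised when an index (I, R, HI, OI) is undefined for the given areas."""


@dataclass
class Pyrogram:
    """A two-stage Rock-Eval record for one sample.

    The pyrolysis ramp (`pyrolysis_temps`, `fid_signal`) is temperature-indexed
    and strictly ascending; the isothermal 200 °C hold that precedes it is
    time-indexed (`hold_times_min`, `hold_fid`) because its temperature axis is
    flat. The oxidation phase carries CO and CO2 infrared signals on its own
    temperature axis.
    """

    pyrolysis_temps: np.ndarray
    fid_signal: np.ndarray
    oxidation_temps: np.ndarray = field(default_factory=lambda: np.array([]))
    co_signal: np.ndarray = field(default_factory=lambda: np.array([]))
    co2_signal: np.ndarray = field(default_factory=lambda: np.array([]))
    hold_times_min: np.ndarray = field(default_factory=lambda: np.array([]))
    hold_fid: np.ndarray = field(default_factory=lambda: np.array([]))
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in ("pyrolysis_temps", "fid_signal", "oxidation_temps",
                     "co_signal", "co2_signal", "hold_times_min", "hold_fid"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.pyrolysis_temps.size == 0:
            raise ValueError("pyrolysis ramp is empty")
        if self.pyrolysis_temps.shape != self.fid_signal.shape:
            raise ValueError("pyrolysis temperature and FID arrays differ in length")
        if np.any(np.diff(self.pyrolysis_temps) <= 0):
            raise ValueError("pyrolysis temperatures must be strictly ascending")
        if self.oxidation_temps.size and (
            self.oxidation_temps.shape != self.co_signal.shape
            or self.oxidation_temps.shape != self.co2_signal.shape
        ):
            raise ValueError("oxidation-phase arrays differ in length")
        if self.hold_times_min.shape != self.hold_fid.shape:
            raise ValueError("hold-phase arrays differ in length")
        for name in ("fid_signal", "co_signal", "co2_signal", "hold_fid"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


@dataclass(frozen=True)
class NodeAreas:
    """A1–A4 window areas as percentages of the total S2 area."""

    A1: float
    A2: float
    A3: float
    A4: float

    def __post_init__(self) -> None:
        vals = (self.A1, self.A2, self.A3, self.A4)
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise ValueError(f"node areas must lie in [0, 100], got {vals}")
        if abs(sum(vals) - 100.0) > 1e-6:
            raise ValueError(f"node areas must sum to 100, got {sum(vals)!r}")


@dataclass(frozen=True)
class TocFactors:
    """Conversion factors assembling TOC (wt %) from the carbon moieties.

    `hc` multiplies S1+S2 (mg HC/g); `co` and `co2` multiply the S3 yields
    (mg/g). The defaults are the standard Rock-Eval 6 stoichiometry: 0.083
    converts hydrocarbons to organic-carbon wt %, and 12/280 and 12/440 carry
    the C mass fraction of CO and CO2 together with the mg/g -> wt % scaling.
    """

    hc: float = 0.083
    co: float = 12.0 / 280.0
    co2: float = 12.0 / 440.0


@dataclass(frozen=True)
class RockEvalResult:
    """Per-sample Rock-Eval parameters plus the Sebag node areas and indices."""

    S1: float
    S2: float
    S3_CO: float
    S3_CO2: float
    TOC: float
    TpkS2: float
    HI: float
    OI: float
    nodes: NodeAreas
    r_index: float
    i_index: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.TOC <= 100.0:
            raise ValueError(f"TOC must be a weight percent in [0, 100], got {self.TOC}")
        if self.HI < 0 or self.OI < 0:
            raise ValueError("HI and OI must be non-negative")
        if not 0.0 <= self.r_index <= 1.0:
            raise ValueError(f"r_index out of [0, 1]: {self.r_index}")

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "S1": self.S1, "S2": self.S2,
            "S3_CO": self.S3_CO, "S3_CO2": self.S3_CO2,
            "TOC": self.TOC, "TpkS2": self.TpkS2,
            "HI": self.HI, "OI": self.OI,
            "A1": self.nodes.A1, "A2": self.nodes.A2,
            "A3": self.nodes.A3, "A4": self.nodes.A4,
            "r_index": self.r_index, "i_index": self.i_index,
        }
        return d


def _window_area(temps: np.ndarray, signal: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid area of `signal` over the temperature window [lo, hi).

    The integral is split exactly at window boundaries by linear
    interpolation, so boundary placement carries no grid-resolution error.
    """
    t0 = max(lo, temps[0])
    t1 = min(hi, temps[-1])
    if t1 <= t0:
        return 0.0
    # Dense knots: original samples inside the window plus the two cut points.
    inside = temps[(temps > t0) & (temps < t1)]
    knots = np.concatenate(([t0], inside, [t1]))
    vals = np.interp(knots, temps, signal)
    return float(np.trapezoid(vals, knots))


def integrate_s2_nodes(p: Pyrogram) -> NodeAreas:
    """Split the S2 pyrogram into the A1–A4 node areas (percent of total).

    Windows are 200–340 (A1), 340–400 (A2), 400–460 (A3) and >460 °C (A4),
    half-open on the right. Raises :class:`UndefinedIndexError` when the total
    area is zero and :class:`ValueError` when the ramp does not reach 460 °C.
    """
    temps, sig = p.pyrolysis_temps, p.fid_signal
    if temps[-1] < 460.0:
        raise ValueError(
            f"pyrolysis ramp ends at {temps[-1]:.1f} °C; must reach 460 °C to define A4"
        )
    areas = {
        name: _window_area(temps, sig, lo, hi) for name, (lo, hi) in A_WINDOWS.items()
    }
    total = sum(areas.values())
    if total <= 0.0:
        raise UndefinedIndexError("total S2 area is zero; node percentages undefined")
    pct = {k: 100.0 * v / total for k, v in areas.items()}
    # Guard the sum-to-100 invariant against float round-off.
    drift = 100.0 - sum(pct.values())
    pct["A1"] += drift
    return NodeAreas(**pct)


def r_index(n: NodeAreas) -> float:
    """Refractory organic-matter index, (A3 + A4) / 100."""
    return (n.A3 + n.A4) / 100.0


def i_index(n: NodeAreas) -> float:
    """Immature organic-matter index, log10((A1 + A2) / A3).

    Undefined (raises :class:`UndefinedIndexError`) when A3 = 0 or A1+A2 = 0.
    """
    if n.A3 <= 0.0:
        raise UndefinedIndexError("I-index undefined: A3 is zero")
    if n.A1 + n.A2 <= 0.0:
        raise UndefinedIndexError("I-index undefined: A1 + A2 is zero")
    return float(np.log10((n.A1 + n.A2) / n.A3))


def compute_parameters(p: Pyrogram, toc_factors: TocFactors | None = None) -> RockEvalResult:
    """Assemble the full Rock-Eval parameter set for one pyrogram.

    S1 integrates the hold-phase FID signal over time (mg HC/g); S2 integrates
    the ramp over temperature; TpkS2 is the ramp temperature at the FID
    maximum; S3 CO / S3 CO2 integrate the oxidation-phase infrared signals
    over their full provided temperature range. TOC sums the three carbon
    moieties through `toc_factors`; HI = 100*S2/TOC and OI = 100*S3_CO2/TOC.
    """
    f = toc_factors or TocFactors()
    s1 = 0.0
    if p.hold_times_min.size >= 2:
        s1 = float(np.trapezoid(p.hold_fid, p.hold_times_min))
    s2 = float(np.trapezoid(p.fid_signal, p.pyrolysis_temps))
    tpk = float(p.pyrolysis_temps[int(np.argmax(p.fid_signal))])
    s3_co = s3_co2 = 0.0
    if p.oxidation_temps.size >= 2:
        s3_co = float(np.trapezoid(p.co_signal, p.oxidation_temps))
        s3_co2 = float(np.trapezoid(p.co2_signal, p.oxidation_temps))
    toc = f.hc * (s1 + s2) + f.co * s3_co + f.co2 * s3_co2
    if toc <= 0.0:
        raise UndefinedIndexError("TOC is zero; HI and OI are undefined")
    hi = 100.0 * s2 / toc
    oi = 100.0 * s3_co2 / toc
    nodes = integrate_s2_nodes(p)
    return RockEvalResult(
        S1=s1, S2=s2, S3_CO=s3_co, S3_CO2=s3_co2, TOC=toc, TpkS2=tpk,
        HI=hi, OI=oi, nodes=nodes, r_index=r_index(nodes), i_index=i_index(nodes),
        sample_id=p.sample_id,
    )


def result_from_parameters(row: dict, sample_id: str = "") -> RockEvalResult:
    """Build a RockEvalResult from pre-integrated parameters.

    For instruments that export S1..TpkS2 and A1–A4 directly, pyrogram
    processing is skipped and the R/I indices are recomputed from the row.
    """
    nodes = NodeAreas(
        A1=float(row["A1"]), A2=float(row["A2"]),
        A3=float(row["A3"]), A4=float(row["A4"]),
    )
    return RockEvalResult(
        S1=float(row["S1"]), S2=float(row["S2"]),
        S3_CO=float(row["S3_CO"]), S3_CO2=float(row["S3_CO2"]),
        TOC=float(row["TOC"]), TpkS2=float(row["TpkS2"]),
        HI=100.0 * float(row["S2"]) / float(row["TOC"]),
        OI=100.0 * float(row["S3_CO2"]) / float(row["TOC"]),
        nodes=nodes, r_index=r_index(nodes), i_index=i_index(nodes),
        sample_id=sample_id or str(row.get("sample_id", "")),
    )


# depth-layer precedence: shallowest applicable label wins
_LAYERS = ("upper50", "below_water_table", "deep", "other")


def classify_depth_layer(
    segment_top_cm: float,
    segment_bottom_cm: float,
    water_table_cm: float,
    clay_top_cm: float,
) -> str:
    """Assign a core segment to one of the analysis depth strata.

    ``upper50``: segment bottom within the top 50 cm; ``below_water_table``:
    segment inside the 50 cm band just below the water table;
    ``deep``: segment inside the deepest 50 cm of peat above the clay contact;
    ``other`` otherwise. A segment matching several rules takes the
    shallowest applicable label.
    """
    top, bottom = float(segment_top_cm), float(segment_bottom_cm)
    if not (0 <= top < bottom <= clay_top_cm):
        raise ValueError(
            f"invalid segment interval ({top}, {bottom}) for clay top {clay_top_cm}"
        )
    if bottom <= 50.0:
        return "upper50"
    if top >= water_table_cm and bottom <= water_table_cm + 50.0:
        return "below_water_table"
    if top >= clay_top_cm - 50.0:
        return "deep"
    return "other"


# ---------------------------------------------------------------------------
# CSV interfaces

_PYRO_COLUMNS = [
    "temp_c", "fid_signal",
    "hold_time_min", "hold_fid",
    "oxid_temp_c", "co_signal", "co2_signal",
]


def write_pyrogram_csv(p: Pyrogram, path: str) -> None:
    """Write one pyrogram to CSV (phase blocks padded with blanks)."""
    n = max(p.pyrolysis_temps.size, p.hold_times_min.size, p.oxidation_temps.size)

    def pad(a: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        out[: a.size] = a
        return out

    df = pd.DataFrame({
        "temp_c": pad(p.pyrolysis_temps), "fid_signal": pad(p.fid_signal),
        "hold_time_min": pad(p.hold_times_min), "hold_fid": pad(p.hold_fid),
        "oxid_temp_c": pad(p.oxidation_temps),
        "co_signal": pad(p.co_signal), "co2_signal": pad(p.co2_signal),
    })
    df.to_csv(path, index=False)


def read_pyrogram_csv(path: str, sample_id: str = "") -> Pyrogram:
    df = pd.read_csv(path)
    missing = [c for c in ("temp_c", "fid_signal") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pyrogram columns {missing}")

    def col(name: str) -> np.ndarray:
        if name not in df.columns:
            return np.array([])
        return df[name].dropna().to_numpy(dtype=float)

    return Pyrogram(
        pyrolysis_temps=col("temp_c"), fid_signal=col("fid_signal"),
        oxidation_temps=col("oxid_temp_c"),
        co_signal=col("co_signal"), co2_signal=col("co2_signal"),
        hold_times_min=col("hold_time_min"), hold_fid=col("hold_fid"),
        sample_id=sample_id or os.path.splitext(os.path.basename(path))[0],
    )


def process_directory(pyrogram_dir: str, toc_factors: TocFactors | None = None) -> pd.DataFrame:
    """Run :func:`compute_parameters` over every ``*.csv`` in a directory."""
    rows = []
    for name in sorted(os.listdir(pyrogram_dir)):
        if not name.endswith(".csv"):
            continue
        p = read_pyrogram_csv(os.path.join(pyrogram_dir, name))
        rows.append(compute_parameters(p, toc_factors).to_dict())
    if not rows:
        raise FileNotFoundError(f"no pyrogram CSVs found in {pyrogram_dir}")
    return pd.DataFrame(rows)
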