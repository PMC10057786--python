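# Methods

`peatsense` implements a coupled organic-geochemistry / remote-sensing
analysis for tropical peatlands: Rock-Eval 6 thermal-stability indices and
carbon stocks from peat cores on one side, normalised-burn-ratio (NBR)
time-series statistics from multi-year reflectance rasters on the other, and
rank statistics joining the two at the site level. Because raw field campaign
data of this kind is rarely redistributable, a first-class synthetic-study
generator produces datasets with the structure the analysis assumes, so every
stage is tested end to end.

## Rock-Eval model

A sample's pyrolysis record has three parts: an isothermal 200 °C hold
(3 min), a ramp from 200 °C to 650 °C at 25 °C/min with FID detection, and an
oxidation phase from 300 °C to 850 °C at 20 °C/min with CO/CO2 infrared
detection. The hold is stored time-indexed (its temperature axis is flat);
the ramp and oxidation phases are temperature-indexed with a 1 °C default
grid.

Parameters:

- `S1` — trapezoid integral of the hold-phase FID curve over time (mg HC/g);
- `S2` — trapezoid integral of the ramp-phase FID curve over temperature;
- `TpkS2` — ramp temperature at the FID maximum;
- `S3 CO`, `S3 CO2` — integrals of the oxidation-phase CO/CO2 curves over
  their full provided range (instrument software uses proprietary cutoff
  windows; we deliberately do not guess them — the windows are configurable);
- `TOC` (wt %) = 0.083·(S1+S2) + (12/280)·S3_CO + (12/440)·S3_CO2. The
  0.083 factor converts hydrocarbons to organic carbon including the
  mg/g → wt % scaling; the CO/CO2 factors combine the 12/28 and 12/44 carbon
  mass ratios with the same scaling. All three are configurable
  (`TocFactors`).
- `HI` = 100·S2/TOC, `OI` = 100·S3_CO2/TOC.

The S2 pyrogram is split into the Sebag temperature nodes A1 (200–340 °C),
A2 (340–400), A3 (400–460) and A4 (>460), expressed as percentages of the
total S2 area. Windows are treated half-open on the right; since the areas
are integrals, boundary assignment only matters at the level of the exact
interpolated split used, which carries no grid-resolution error (the
integral is cut at the window boundary by linear interpolation). From the
node percentages:

- R-index = (A3 + A4)/100 — refractory fraction, in [0, 1];
- I-index = log10((A1 + A2)/A3) — immature (labile) excess.

We read the R-index as (A3+A4)/100 rather than the literal A3 + A4/100:
A-values are percentages, the I-index uses the same percentage convention,
and the literal reading would exceed 1 for any realistic peat. The I-index is
undefined when A3 = 0 or A1+A2 = 0; such samples are flagged and excluded
from summaries with a count, never silently dropped.

No multi-Gaussian curve fitting is performed: node areas integrate the
observed curve directly. Index behaviour is monotone in the intended
direction — moving mass from A1/A2 to A3/A4 at constant total strictly
raises R and lowers I — which is the degradation signature the analysis
relies on.

Depth strata: each 10 cm segment is labelled `upper50` (bottom within the top
50 cm), `below_water_table` (inside the 50 cm band below the water table),
`deep` (inside the deepest 50 cm above the clay contact) or `other`; a
segment matching several rules takes the shallowest applicable label. Litter
samples are carried with the label `litter` and excluded from stocks and
strata comparisons.

## Carbon accounting

Bulk density = oven-dry mass / chamber volume. The default volume,
98.17 cm^3 per 10 cm increment, is the half-cylinder chamber of a
2.5 cm-radius corer (π·2.5²·10/2); it is a configuration default, not a
hard-coded constant, since other corers differ. Per-segment carbon density =
bulk density × (TOC/100) × thickness (g cm^-2); core stock is the sum over
the profile, converted with 1 g cm^-2 = 100 Mg ha^-1 (1 g cm^-2 = 10^4 g
m^-2 = 10^8 g ha^-1). The upper-50 cm stock restricts the sum to segments
whose bottom lies within 50 cm.

Rock-Eval is typically run on selected sub-samples only, so unmeasured
segments take TOC linearly interpolated between measured neighbours by
segment-midpoint depth, constant-extrapolated at the core ends. Vegetation
carbon = 0.47 × above-ground biomass (Mg ha^-1).

## Remote sensing

NBR = (NIR − SWIR2)/(NIR + SWIR2) per pixel and year; pixels with zero band
sum or nodata propagate NaN. Stack statistics are the pixelwise mean and the
sample (n−1) standard deviation over valid years — the sample convention
matching the R `raster` stack statistics commonly used for this product —
with sd set to nodata below two valid years. A Shapiro–Wilk check runs on a
seeded random sample of pixel series (not all pixels) and reports W, p and
the rejection fraction at α = 0.05; constant series are flagged undefined.

Site extraction is nearest-pixel (the containing cell of the point), with no
interpolation or neighbourhood averaging. Distances to the river and canal
networks are planar minimum point-to-polyline distances (shapely) and
require a projected metric CRS; geographic coordinates are rejected rather
than silently mis-measured. Scenes must be pre-co-registered; no resampling
is implemented.

Raster IO uses plain TIFFs with the affine georeferencing, CRS tag and band
names carried as a JSON payload in the image description, which round-trips
losslessly through `tifffile`.

## Rank statistics

- Spearman: mid-rank ties; S = Σ(rank_x − rank_y)²; rho from
  1 − 6S/(n(n²−1)) without ties and from Pearson-on-ranks with ties (the two
  coincide when tie-free); two-sided p via the t approximation.
- Two-group comparison: W = Mann–Whitney U of the first group
  (Σ pooled ranks of group a − n_a(n_a+1)/2, range [0, n_a·n_b]), the
  convention of R's `wilcox.test`. Exact two-sided p when n_a·n_b ≤ 400 and
  tie-free, else normal approximation with continuity correction. The
  sometimes-seen "d.f. = 1" notation for rank-sum tests has no standard
  meaning and is not emulated.
- Kruskal–Wallis: tie-corrected H against chi-squared with k−1 df;
  all-identical data is reported as undefined rather than raised, so
  screening loops keep going.
- Pairwise Wilcoxon with Bonferroni: all k(k−1)/2 comparisons,
  p_adj = min(1, p·m).
- All tests are two-sided.

## Synthetic-study generator

The generator is the study-condition definition, not a tuning knob. A
campaign defaults to 11 cores — 3 Central Forest, 2 Managed Recovery, 4
Disturbed Forest, 2 Fire Affected — and a 5-year scene stack (1989, 1995,
2001, 2010, 2019) on a 60×60-pixel, 30 m grid in a projected CRS.

Each sample's S2 curve is a truncation-normalised Gaussian mixture of four
pools (labile plant matter, lignin/cellulose, humified macromolecules,
recalcitrant/char) centred at 310/370/430/500 °C — mid-window placements for
A1–A3 and a representative >460 °C centre for the char pool — with σ 15/15/
15/20 °C. Undisturbed profiles mature linearly with depth (labile fractions
falling, refractory rising), calibrated so a pristine column spans roughly
R 0.50→0.64 and I 0.19→0.0 from the surface to 3.5 m, in the range reported
for intact ombrotrophic tropical peat. Disturbance multiplies the two labile
pools of the upper 50 cm by (1 − depletion) before renormalisation, and also
scales the target HI and TOC of those segments by (1 − 0.35·depletion),
standing for the dehydrogenation and carbon loss of oxidised surface peat.
Class defaults (depletion / NBR level / NBR temporal sd / mean AGB): Central
Forest 0, 0.55, 0.03, 280; Managed Recovery 0.35, 0.40, 0.08, 180; Disturbed
Forest 0.30, 0.35, 0.10, 120; Fire Affected 0.45, 0.25, 0.13, 60. A single
`class_contrast` factor scales every between-class difference; 0 yields a
null dataset used for type-I calibration.

Bulk density draws from N(0.10, 0.008) g cm^-3 (clipped to [0.06, 0.14]);
dry-mass fraction of wet mass from N(0.12, 0.01). Core depth is uniform on
[1.0, 3.5] m for every class (within-class depth variability is a free
parameter; using one range for all classes keeps whole-profile stock
independent of condition class, mirroring the observed null for total-profile
correlations). The water table defaults to 0.4 m below the surface (dry
season); oxidation CO/CO2 curves are single Gaussians whose masses close the
TOC budget — their shape is illustrative plumbing for the TOC/OI assembly,
with no literature claim. Rock-Eval sub-samples are taken on alternating
increments plus the deepest one, and each core carries one litter sample
with a labile-dominated composition (I ≈ 0.74).

Sites sit on a jittered grid inside the raster extent, one pixel each;
coinciding site pixels are rejected. Pixels in a 3-pixel-radius disc around
each site carry the class NBR level and year-to-year variability; NBR maps to
reflectance through a fixed NIR+SWIR2 budget of 0.5, keeping reflectance in
[0, 1]. A meandering river crosses the extent and one canal line runs near
each Disturbed Forest / Fire Affected site. All randomness flows from one
seeded `numpy` generator, so a fixed seed reproduces every output file byte
for byte.

What the generator does **not** emulate: radiative transfer, clouds and
atmospheric effects, vegetation growth, peat hydrology, spatial
autocorrelation of disturbance, mixed mineral horizons, or instrument drift.
Passing tests therefore demonstrate that the pipeline recovers structure it
is pointed at, under clean conditions — not that the method is robust to the
full messiness of field data.

## Pipeline and reporting

`run_analysis` chains simulate (or load) → Rock-Eval → stocks → NBR →
correlations, and reports: per-sample I/R and HI/OI tables; class-by-layer
medians and IQRs (linear-interpolation quartiles, R type 7), including the
pooled "disturbed" grouping (Fire Affected + Disturbed Forest + Managed
Recovery); Kruskal–Wallis and pairwise-Bonferroni class tests for the upper
50 cm and the combined below-water-table + deep strata; and a Spearman
screen of upper-50 stock vs NBR sd, upper-50 HI vs NBR mean, and
whole-profile stock/parameter medians vs all four covariates (NBR mean, NBR
sd, river distance, canal distance). Empty class-layer cells are absent, not
zero; undefined indices are excluded with a count in the report. Rerunning
from persisted stage outputs reproduces the in-memory end-to-end run.

## Problem sizes and numerical choices

Replicated checks use 100 paired cores for the I-index contrast, 100
end-to-end runs for the directional sign fraction, and 100 null runs for
type-I calibration; the calibration band is ±3 binomial sigma around the
nominal 0.05. The temperature grid step is 1 °C (halving it moves S2 by
<0.1%); node integrals are split exactly at window boundaries; synthetic FID
noise defaults to ~2% of a typical peak height. The rank-sum p switches from
exact enumeration to the continuity-corrected normal approximation above
n_a·n_b = 400 or in the presence of ties.

## Limitations

Pre-integrated input mode trusts the instrument's A1–A4 and recomputes only
the indices. The S3 integration windows of commercial instrument software
are not reproduced. No uncertainty propagation beyond per-core values; no
spatial autocorrelation correction in the rank tests; single-pixel site
extraction ignores neighbourhood context. The synthetic generator's
parameter choices are fixed, documented conditions — results on real field
data depend on properties the generator does not emulate.
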