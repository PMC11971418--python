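# Methods

## Model

Annual cropland water-use efficiency is defined as NPP/ET (g C per kg of
water per year). The chain is: daily GPP from the evaporative-fraction
light-use-efficiency (EF-LUE) model; daily maintenance respiration (MR)
from LAI-derived leaf and fine-root carbon pools; annual closure
`NPP = max(0, (ΣGPP − ΣMR)/(1 + g))` with growth respiration `GR = g·NPP`
and `g = 0.25`, so the factor is 0.8; annual ET as the sum of the daily ET
product; WUE as the per-pixel (or per-site) ratio.

Daily GPP is `fAPAR · PAR · ε_max · F_T · F_VPD · F_W` with
`PAR = 0.48 · shortwave`. The temperature factor is the parabolic quotient
`(T−Tmin)(T−Tmax) / [(T−Tmin)(T−Tmax) − (T−Topt)²]`, fixed cutoffs
Tmin = 0 °C and Tmax = 40 °C, and is set to 0 outside the cutoffs; at the
cutoffs the quotient itself vanishes, so returning 0 there keeps the
response continuous. The VPD factor is `VPD₀/(VPD₀+VPD)` with VPD from the
Tetens saturation curve evaluated at air and dew-point temperature. The
water factor is the evaporative fraction `λET/(Rn−G)` clamped to [0, 1].

Assumptions worth keeping in mind: stress factors are multiplicative and
independent; λ is a constant 2.45 MJ/kg; respiration is leaves plus fine
roots only (no stem/live-wood term — adequate for herbaceous crops, not for
woody vegetation); nitrogen, salinity and carbohydrate-status effects on
respiration are not modelled; C3/C4 differences enter only through the
per-zone calibration, not explicitly.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| ε_max | maximum light-use efficiency | g C/MJ | calibrated per zone |
| T_opt | optimum air temperature | °C | calibrated per zone |
| VPD₀ | half-saturation VPD | kPa | calibrated per zone |
| T_min, T_max | photosynthesis cutoffs | °C | 0, 40 (fixed) |
| par_fraction | PAR / shortwave | – | 0.48 |
| magnus_coef | Tetens exponent coefficient | – | 17.27 (12.27 selectable) |
| λ | latent heat of vaporization | MJ/kg | 2.45 |
| Leaf_mr_base | leaf MR per unit leaf C at 20 °C | kg C/kg C/d | 0.0098 |
| Froot_mr_base | fine-root MR at 20 °C | kg C/kg C/d | 0.00819 |
| SLA | specific leaf area | m²/kg C | 30.4 |
| Froot_leaf_ratio | fine-root : leaf carbon | – | 2.0 |
| Q10 (fine root) | respiration temperature sensitivity | – | 2.0 |
| Q10 (leaf) | temperature-dependent | – | 3.22 − 0.046·Ta, floored at 0.1 |
| gr_fraction | GR as fraction of NPP | – | 0.25 |

The `magnus_coef` field exists because the coefficient appears in print in
two variants; 17.27 is the standard Tetens value and the default. Every
result in this package is computed with it unless explicitly configured
otherwise, and no shipped number depends on the choice at the precision
reported. The leaf-Q10 floor (0.1) only matters above 68 °C, outside any
cropland record; it exists so the linear form cannot produce a negative
sensitivity.

Calibration solves a box-bounded nonlinear least-squares problem on daily
GPP residuals with the Trust Region Reflective algorithm (scipy
`least_squares`), start point (3.8, 28.0, 1.2), bounds (0, 0, 0)–(24, 35, 3),
`ftol = xtol = 1e-8`, at most 1000 function evaluations, and requires at
least 30 valid pooled days. Days with missing observations or drivers are
dropped, not imputed. Zero observation variance is flagged as
non-identifiable in the results rather than raising, since the optimizer
still returns a well-defined (boundary) point. Per-zone pooling of all
sites in a zone is the production path — it is what produces a one-row-per-
zone table — with independent per-site fits available as a diagnostic mode.

## Synthetic data

The generator emulates the *structure* of the production inputs, not their
climatology: daily air/dew-point temperature, shortwave, ET, net radiation
and soil heat flux with a mid-latitude seasonal cycle (annual-mean Ta
12 °C, amplitude 14 °C, Gaussian day-to-day noise of 2 °C, so summer daily
means approach 30 °C as they do over temperate maize/wheat sites); 8-day
fAPAR/LAI composites with a growing-season hump peaking near day 200;
dew-point always at or below air temperature; evaporative fraction mostly
inside [0, 1] with occasional exceedance up to 1.04 to exercise the clamp;
a small fraction (2 %) of days with negative available energy to exercise
the F_W fallback. Observed GPP is model GPP under a known truth triple plus
zero-mean Gaussian noise with standard deviation equal to 5 % of the mean
modelled GPP (truncated at zero), the noise level used throughout the
recovery experiments.

Rasters are deliberately blocky: climate zones are contiguous horizontal
bands; one driver series is shared within each zone band; vegetation gets a
smooth per-pixel scale in [0.8, 1.0]. The fine land-cover grid uses an
exact integer block factor (default 3) relative to the analysis grid so
the >50 % majority rule is exactly testable; the real 300 m → 1 km ratio is
not integer, but the rule is about coverage fraction, not resampling
geometry. The fine cropland count per coarse cell is the nearest integer
to fraction × factor², so requested coverage is realized to within
1/factor².

Consequently, passing tests demonstrate the correctness of the numerical
chain, the masking rules and the identifiability of the parameters under
the stated noise — not fidelity to real ERA5/GLASS/ETMonitor statistics,
real spatial autocorrelation, or real flux-partitioning conventions of
tower GPP.

## Numerical choices

- Units: MR is computed in kg C/m²/d and converted ×1000 to g C/m²/d before
  the annual sum, so it subtracts from GPP in shared units. Energy for the
  evaporative fraction converts mean daily W/m² to MJ/m²/d via 0.0864.
- `Rn − G ≤ 0`: EF is undefined; F_W falls back to 0 (no energy to drive
  transpiration-coupled assimilation), with the day count logged.
- Annual sums require complete calendar years (365/366 layers, Feb 29
  included); nodata propagation is strict by default (any missing day
  voids the pixel), with a tolerant mode that sums available days and logs
  coverage.
- WUE masking: non-cropland pixels, ET ≤ 0 and WUE > 50 g C/kg H₂O/yr all
  become nodata; the cropland-majority threshold is strictly greater than
  50 % (exactly half is not cropland).
- 8-day → daily interpolation is linear between nodes with terminal-value
  hold outside the node range; node values are preserved exactly.
- GeoTIFFs are single-band float32, EPSG:4326, north-up pixel-is-area,
  nodata −9999, written without timestamps so identical inputs give
  byte-identical files. In memory, NaN is the missing-value sentinel.
- Raster and site modes share one GPP kernel, evaluated zone-by-zone on the
  raster, so a one-pixel raster reproduces a site run to within round-off.

## Problem sizes

Desk-scale defaults keep everything fast and deterministic: 12×12 (tests)
to 24×24 (acceptance script) analysis grids with a 3× fine land-cover
factor, one-year daily stacks, 3-site networks for recovery experiments
(≈1095 pooled days per fit) and 20 replicate seeds for the noisy-recovery
medians. The full acceptance script completes in a few seconds on one CPU.

## Known limitations

- The Kling–Gupta efficiency uses the 2009 equal-weights form; the 2012
  variability-ratio variant is not implemented.
- No uncertainty intervals on calibrated parameters (point estimates only),
  and no cross-validation machinery.
- T_opt is weakly identified when a zone's temperature record never
  approaches the optimum; the bounded fit then returns a boundary-adjacent
  value while ε_max and VPD₀ remain well constrained. This mirrors the
  situation with real warm-optimum zones observed only in cool records.
- No tiling or distributed execution: raster mode holds one year of daily
  stacks in memory, which is ample at desk scale but not at global 1-km
  scale.
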