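# Methods

## Scope and data model

The package implements a single-scene surface-energy-balance ET retrieval
(METRIC-style) plus the station-side ground-truth chain and agreement
statistics. Rasters are 2-D float arrays with NaN as missing data; a `Grid`
records pixel size and origin. On disk a band is a float32 TIFF (nodata
−9999) with a JSON grid sidecar; the thermal band, if coarser than the
reflectance grid, is resampled to it by nearest neighbour at ingest. All
temperatures are kelvin internally; Celsius appears only at I/O and in
reports. Band roles (Landsat 7 bands 3/4 vs Landsat 8 bands 4/5) are
resolved at ingest so the math is band-agnostic.

## Retrieval chain and assumptions

**SAVI → LAI.** LAI = −ln((0.69−SAVI)/0.59)/0.91, clamped to [0, 6]. SAVI
below 0.10 (raw LAI negative) clamps to 0 rather than masking: bare soil is
valid scene content. SAVI at or beyond the logarithm's domain maps to
exactly 6. Clamps are counted and logged. The forward inverse
SAVI = 0.69 − 0.59 e^(−0.91 LAI) is exposed for the synthetic generator;
the retrieval is exact below the cap and undefined above it, which is why
the zero-noise oracle season keeps its canopy peak below 6.

**Emissivities.** For NDVI > 0: ε_NB = 0.97 + 0.0033 LAI and
ε₀ = 0.95 + 0.01 LAI up to LAI = 3, both 0.98 above. The model has a small
(≤ 1e-4) step at the LAI = 3 boundary, kept as published. NDVI ≤ 0 pixels
take (0.99, 0.985); water vs snow is distinguished only by an albedo
threshold (0.47) recorded in a classification tag, since both branches share
values.

**Surface temperature.** Ts = K₂/ln(ε_NB K₁/R_c + 1). Defaults
K₁ = 666.1, K₂ = 1282.7 (Landsat 7 band 6) and K₁ = 480.9, K₂ = 1201.1
(Landsat 8 — note these published values match the Band 11 constants though
labelled Band 10 in the source material; a config override and a logged
warning cover the discrepancy). The atmospheric correction
R_c = (L_sensor − R_p)/τ_NB − (1−ε_NB) R_sky defaults to the identity
(τ = 1, R_p = R_sky = 0): with no sounding data the at-sensor radiance is
taken as surface-leaving, which is the regime the calibration is designed to
absorb.

**Net radiation and soil heat flux.** Rn per the five-term shortwave/
longwave assembly with RL↑ = ε₀σTs⁴; RL↓ either supplied or from the
clear-sky parameterization ε_a = 0.85(−ln τ_sw)^0.09,
τ_sw = 0.75 + 2·10⁻⁵·z. G/Rn = 0.05 + 0.18 e^(−0.521 LAI) for LAI ≥ 0.5,
else 1.80(Ts−273.16)/Rn + 0.084; the boundary belongs to the dense branch.

**Sensible heat and internalized calibration.** dT(z₁ = 0.1 m → z₂ = 2 m)
is linear in Ts. Anchors: the cold pixel is the coolest among the top-5%
NDVI population, the hot pixel the warmest among the bottom-10%, ties broken
row-major; manual coordinates override. Anchor ET fractions are the
canonical 1.05 (cold) and 0.0 (hot), config-exposed. Wind is lifted from the
station anemometer (roughness 0.03 m by default) to a 200 m blending height
and brought down per pixel over z_om = max(0.018 LAI, 0.005) m. The
Monin–Obukhov loop recomputes the Obukhov length from current H, applies the
integrated ψ corrections (unstable: x = (1−16z/L)^0.25 forms; stable:
−5z/L), updates u* and r_ah, and refits (a, b); convergence is declared when
the line moves less than 10⁻³ K (max |Δa|, |Δb|·Ts_hot).

Numerical guards, each of which mattered in practice:

- the r_ah update is under-relaxed (new ← ½ new + ½ old); plain successive
  substitution oscillates in strongly unstable low-wind scenes;
- the iteration cap is 30 passes: from a neutral cold start on ~1 m s⁻¹
  days the damped iteration contracts smoothly but needs ~20–28 passes to
  reach the 10⁻³ K tolerance;
- the stable-branch correction caps z/L at 1 (strongly-stable limit).
  Without the cap, the slightly stable cold anchor (H < 0, small u*) drives
  its resistance to the clamp and the fitted dT slope to unphysical values;
- |H| < 10⁻⁶ W m⁻² pixels take the neutral limit (ψ = 0), and r_ah is
  clipped to [1, 1000] s m⁻¹.

dT is regressed against raw Ts with no elevation-datum adjustment: the
emulated field spans ~9 m of relief, for which a lapse correction is
negligible. Air density comes from the ideal-gas law at station pressure
P = 101.3((293−0.0065z)/293)^5.26 kPa, falling back to 1.15 kg m⁻³.

**ET products.** LE = Rn − G − H exactly (closure is an identity, asserted
to 10⁻⁶ W m⁻² in tests). Negative LE is preserved in the flux rasters
(advection and edge pixels are diagnostic) but clamps to 0 at ET_inst, with
a counter. ETrF is left unclamped; values above 1.3 are counted. Seasonal ET
linearly interpolates ETrF per pixel between image dates and multiplies by
daily ETr₂₄; outside the image span the nearest image value is held
constant, since nothing supports trend extrapolation.

## Ground-truth arm

Reference ET uses the ASCE standardized Penman–Monteith tall-crop form
(daily C_n = 1600, C_d = 0.38; hourly C_n = 66, C_d = 0.25 day / 1.7
night); an independent straight-line transcription of the same form serves
as the test oracle, and the config path also accepts externally supplied ETr
directly. The Kc curve is piecewise linear on a days-after-emergence axis
with default knots (0, 0.25) → (55, 1.0) → (95, 1.0) → (120, 0.5): the
0.25 initial value, the peak of 1.0 at effective cover (55 DAE), and the
0.5 end-of-season value approximate a published corn curve's *shape*; they
are data, editable in config, not tabulated study values. Weather QC is a
flag-don't-impute screen: range checks (RS↓ ∈ [0, 1367] W m⁻²,
Ta ∈ [−40, 50] °C, u ∈ [0, 30] m s⁻¹, e_a ≥ 0) and strict timestamp
ordering; flagged records are excluded from ETr computation. Fuller
solar-envelope QC procedures are out of scope.

## Agreement statistics

r² is the squared Pearson correlation of (estimated, measured) — the only
reading consistent with the recomputable published values. MBE is the signed
mean of (estimated − measured), with |MBE| also surfaced since published
magnitudes omit the sign. Both the paired RMSE √(mean (x−y)²) and the
regression standard error √(S_yy(1−r²)/(n−ddof)) are first-class outputs:
on the shipped LAI table the published "RMSE" of 0.59 is reproducible only
as the regression SE (ddof = 1), while the paired RMSE is 0.94; the two
coincide only when the fitted line is the identity. On the shipped Ts table
the paired statistics give MBE +0.78 °C and RMSE 1.59 °C. Model values at a
plot are nine-pixel (3×3) block means centred on the plot pixel; blocks
clipped by the raster edge or mask produce a flagged partial mean.

## Synthetic season generator

The generator emulates the study conditions rather than radiative-transfer
realism: a 40×40, 30 m grid; six overpasses (DOY 178–258) alternating
sensors; five named 3×3-pixel plots, two of them (N, S-E) with a moisture
deficit (LAI × ~0.9, surface +1 K) consistent with their higher landscape
position; a logistic LAI trajectory from ~0.3 through a 6.8 peak to 3.5 at
season's end; surface temperatures spanning roughly 19–31 °C; one high-wind
overpass (5.9 m s⁻¹, DOY 194) against ~1.0 m s⁻¹ on the others; reference
ET from the package's own standardized equation applied to smooth seasonal
forcing (clear-sky shortwave, mid-continent air temperature, 50% relative
humidity), giving ETr₂₄ of roughly 5–10 mm day⁻¹.

Scenes are built by exact forward inversion: reflectances from the SAVI
inverse with a soil-line split (red = 0.25 − 0.028 LAI, clamped ≥ 0.02; NIR
solved from the SAVI identity — any split satisfying the identity would do,
and the soil line yields plausible NDVI), thermal radiance from the Planck
inverse at the generated Ts, albedo declining mildly with canopy. Spatial
texture is seeded correlated Gaussian noise (correlation length 3 px). Two
extreme pixels are planted — full-cover coolest and bare warmest — so the
automatic anchor search is unambiguous and the truth energy balance
(computed with the same operators, neutral stability) satisfies the
calibration's anchor assumptions exactly. Plot "measurements" are 3×3 block
means of truth plus instrument noise: LAI sd 0.3 (ceptometer), Ts sd 0.5 °C
(a ±2 °C infrared thermometer averaged over ten readings), ETa sd
0.35 mm day⁻¹ (the atmometer-plus-Kc error level). A field-uniform Kc curve
cannot produce between-plot ETa variance within a date, so plot ETa truth is
taken from the energy-balance truth rasters while the Kc×ETr computation
itself lives (and is tested) in the reference module.

What passing tests show — and what they do not: zero-noise round trips prove
the pipeline inverts its own forward model exactly (plumbing, unit handling,
anchor selection, calibration algebra), and noisy seasons show the agreement
statistics behave sensibly under instrument-scale noise. They do not
validate the physics against real scenes: atmospheric effects, sensor PSF,
gap artifacts, clouds, and soil-moisture dynamics are all outside the
generator.

## Problem sizes and determinism

Default test and acceptance runs use the 40×40 six-date season; a full run
(generation, processing with stability iteration, statistics) completes in
seconds. Every random draw flows from `numpy.random.default_rng` seeded by
the season seed plus a per-stream offset, so a seed fully determines scenes,
weather, and measurements; equal seeds give bit-identical output.

## Known limitations

- No terrain radiation or lapse-rate dT datum; desk-scale flat fields only.
- No excess-resistance (kB⁻¹) refinement; z_oh enters only through the
  fixed z₁ = 0.1 m formulation.
- The atmospheric thermal correction defaults to identity; supplying
  τ_NB/R_p/R_sky is the user's responsibility when soundings exist.
- The Kc default knots are shape placeholders, not calibrated values.
- ETrF interpolation between overpasses is linear; no soil-water-balance
  adjustment between image dates.
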