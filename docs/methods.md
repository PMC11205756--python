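# Methods

## The saturating absorbance–concentration model

Optical density of an algal suspension is not Beer–Lambert linear at high
cell density: once cells begin to shade one another, each added cell
contributes less absorbance than the last. Modelling the marginal
contribution as proportional to the remaining headroom,

    dA/dc = k · (A_max − A),

with A(0) = 0 for the solvent blank, gives

    A(c) = A_max · (1 − e^(−k·c)),

the Box–Lucas law with asymptote A_max (the absorbance of a fully
self-shading suspension, typically 3–4 AU depending on instrument) and
specific light absorption coefficient k per (mg d.m./L). For k·c ≪ 1 it
reduces to A ≈ A_max·k·c, the familiar linear regime, with initial slope
A_max·k. The inverse

    c = ln(1 − A/A_max) / (−k)

is the biomass estimator; it diverges as A → A_max, so readings at or
above the asymptote are rejected with the advice to dilute and remeasure.

Shipped defaults (A_max = 3.29, k = 0.0022 at 440 nm) describe one
specific *C. vulgaris* culture measured on one spectrophotometer. They
are named constants, not physics: every estimator accepts user-fitted
values, and `fit_box_lucas`/`compare_models` exist precisely to refit
them per culture and instrument.

## Correlation scanning

For each laboratory density parameter, the scanner runs an ordinary
least-squares regression of blank-corrected absorbance (response) on the
parameter (predictor) at every wavelength of a 1 nm grid, default
300–1100 nm (801 regressions; the grid is configurable, e.g. 190–1100 nm
for instruments that scan into the UV, where absorbance saturation makes
the data useless for calibration anyway). The regression is the
closed-form OLS with r² the squared Pearson correlation, so the r² curve
is invariant under axis swap and under affine rescaling of the parameter.
`best_wavelength` takes the r² argmax, ties resolved to the lowest
wavelength. Degenerate columns (constant absorbance, e.g. a dead
detector region) score r² = 0 with a warning instead of aborting, so a
scan always yields a complete table.

Below-LOD censoring is parameter-specific and applied before the scan:
on the packaged reference series, evaporation biomass loses the
200×–1000× rows and filtration biomass the 1000× row, while Mg keeps all
ten rows.

Note on the reference correlation table: recomputing the printed
correlation values from the packaged series yields their squares
(0.99750 for ratio–filtration biomass vs the quoted 0.99875, etc.),
i.e. the quoted figures are |r| rather than r². This package reports the
true coefficient of determination; the acceptance tolerances absorb the
difference.

## Nonlinear fitting

`fit_box_lucas` uses Levenberg–Marquardt with starting values
a₀ = 1.05·max(y) and b₀ from OLS on the linearisation −ln(1 − y/a₀) vs
x; relative parameter tolerance 1e-10, function-evaluation cap 1500.
r² for both families is computed in the original response space
(1 − SSE/SST) so linear and saturating fits are directly comparable;
`compare_models` prefers the higher r² and resolves ties within 1e-9 to
the linear family (parsimony — the saturating family nests the line
through the origin).

Data confined to the pre-saturation regime leave A_max unidentified (a
flat ridge a → ∞, b → 0 at fixed a·b), on which Levenberg–Marquardt
cannot terminate. The fit then falls back to a bounded 1-D minimisation
over b ∈ [1e-12/x_max, 50/x_max] with the conditionally optimal
a(b) = (yᵀf)/(fᵀf), f = 1 − e^(−b·x), profiled out in closed form. The
fallback converges to the ridge edge: a huge A_max whose product with k
equals the line's slope, and an r² equal to the linear fit's to
numerical precision. Genuine non-convergence raises, never returns
silently.

## Stoichiometric derivations

Each chlorophyll-a molecule binds exactly one Mg atom, so a measured Mg
concentration (µg/L) implies at most
Mg × (893.5 g/mol ÷ 24.3 g/mol) = Mg × 36.77 µg/L of Chl a. Comparing
this ceiling with directly extracted Chl a validates the Mg
measurement. Mg per 100 g dry matter is Mg[µg/L]/biomass[mg/L] × 100;
single-cell weight is biomass[mg/L]×1000 / cellnumber[10⁶ cells/L] in µg
per 10⁶ cells. `summarize_derived` averages these over dilutions up to
10× by default (mean ± sample sd, ddof = 1): at higher dilution the
evaporation residue and ashed Mg sit too close to instrument noise for a
meaningful ratio. (The exclusion threshold is a parameter; descriptions
of the underlying measurements variously suggest 10× or 20× as the
cutoff, and the default follows the rows actually used in the reference
summary.)

The trichromatic (Felföldy-style) extract formula
chla = (c₁·(A666 − A750) − c₂·(A653 − A750))·factor ships with **no
default coefficients**: the constants depend on the extraction protocol
and pathlength, and inventing them would misattribute someone else's
calibration. Supply them via `FelfoldyCoefficients`.

Pairwise correlations mimic spreadsheet trendlines, which is how such
tables are produced in practice: linear (OLS), logarithmic (OLS of y on
ln x) and exponential (OLS of ln y on x), each r² reported in the space
the line was fitted in, best family by r². Users wanting original-space
r² for the transformed families can fit those curves directly with the
calibration module.

## Cell counting

The pipeline mirrors the standard image-tool recipe on brightfield
chamber images (dark cells, light uneven background):

1. **Background subtraction** — the image is presmoothed with a 3×3
   median (as rolling-ball implementations do; without it, the
   morphological envelope of pixel noise acquires a ~+3σ bias that eats
   the fixed-threshold margin) and the background is estimated by
   grayscale closing (light background) or opening (dark background)
   with a decomposed disk footprint, default radius 50 px, then
   subtracted. A border strip one radius wide retains an edge artifact,
   as with any morphological background estimate.
2. **8-bit conversion** — min–max rescale to [0, 255]; a constant image
   maps to zeros with a warning.
3. **Threshold** — keep pixels with intensity in [0, 200] (defaults;
   both bounds configurable).
4. **Particle analysis** — 8-connected components with pixel area in
   [6, 150]. The published recipe prints the size range as "6150
   pixels"; this package reads that as 6–150 px (an en-dash lost in
   typesetting) — if your cells at your magnification are larger, set
   `min_area`/`max_area` accordingly. Border-touching particles are kept
   by default (`exclude_border` switches this).
5. **Concentration** — count / (analyzed_area[mm²] × depth[mm] × 10⁻⁶ L)
   × dilution factor. Defaults: 0.64 mm² analyzed area and the standard
   Bürker depth of 0.1 mm.

Degenerate-threshold guard: on a field with no objects, the min–max
stretch amplifies pure noise and the fixed band then covers essentially
the whole frame. If the thresholded foreground exceeds half the image,
the pipeline reports zero particles with a warning rather than counting
noise islands.

## Synthetic data

The spectral generator applies the saturating law independently per
wavelength: A(λ, c) = A_max(λ)·(1 − e^(−k(λ)·c)), with both profiles
shaped by Gaussian pigment peaks (defaults near 440 and 680 nm, the blue
and red chlorophyll bands — qualitative stand-ins, not measured values)
above small baselines, scaled so the 440 nm point matches the shipped
calibration constants. Noise channels: per-wavelength multiplicative
Gaussian (replicate scatter grows with signal; switchable to additive)
and per-scan additive offsets (`scan_offset_sd`, baseline drift between
cuvette insertions).

The drift channel is what makes the wavelength-selection property
testable: with per-wavelength noise exactly zero, the per-wavelength r²
ordering is governed by saturation curvature and peaks where k(λ) is
*smallest* (the featureless IR tail), not where sensitivity is greatest.
Under wavelength-independent drift in the dilute regime, the residual of
the regression is identical at every wavelength while the signal
variance scales with sensitivity², so the r² argmax coincides exactly
with the generator's mean-∂A/∂c argmax (`sensitivity_argmax`). Tests of
that property therefore use dilute-regime series (k·c ≤ ~0.1) with small
drift.

The dilution-series generator scales stock parameter values (defaults
matching the packaged reference stock: 960 mg/L evaporation biomass,
1.08 × 10¹¹ cells/L, etc.) by the ratio list (1, 0.5, … 0.001), applies
optional per-parameter noise and LOD censoring, and pairs each dilution
with replicate spectra driven by the implied biomass.

Chamber scenes are dark non-overlapping disks (radius ~N(4, 0.8) px
clipped to [2.5, 6] so true areas stay inside the default 6–150 px
band), placed by rejection sampling (cap 10⁴ attempts per disk) on a
light background (level 0.85) with a linear illumination ramp (amplitude
0.12) and additive pixel noise (sd 5/255), default 384×384 px — sized
like a cropped chamber field at moderate magnification, and small enough
that hundreds of scenes run in well under a minute. All generators are
bit-reproducible under a fixed seed.

What the synthetic fixtures do *not* emulate: optical blur and
out-of-focus cells, overlapping or touching cells (no watershed
splitting is attempted), debris with cell-like size, wavelength-correlated
instrument noise, and stray-light/bandwidth effects. Passing the scene
benchmark therefore demonstrates the pipeline's correctness and its
robustness to uneven illumination and pixel noise, not performance on
crowded or defocused real micrographs.

## Numerical notes

- `saturation_absorbance`/`estimate_biomass_od440` use `expm1`/`log1p`
  for small-argument accuracy; the round trip is exact to 1e-9 relative
  over c ∈ [0.1, 3000].
- OLS r² is 0 by definition when the response is constant.
- Spectra on different grids are regridded by linear interpolation onto
  a common 1 nm grid (intersection of spans) before set operations; the
  blank is subtracted from the replicate average (identical to per-
  replicate subtraction for a pointwise mean, but that order is the
  documented one).
- Negative post-blank absorbances are kept; clipping would bias
  low-concentration regressions.

## Known limitations

- The default calibration constants are culture- and instrument-specific;
  using them unrefitted on another setup gives systematically biased
  biomass.
- The Mg → Chl a conversion is an upper bound (assumes all cellular Mg
  is chlorophyll-bound); at high dilution the comparison with extracted
  Chl a degrades with instrument noise.
- The counting pipeline does not split touching cells; at high surface
  densities it undercounts.
- Correlation-scanning wavelength choices inherit the dilution series'
  noise structure; a series with strongly wavelength-correlated errors
  can shift the r² peak.
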