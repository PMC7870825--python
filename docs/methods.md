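# Methods

## Problem setting

A plot trial is imaged by UAV one day before each harvest. The input to the
pipeline is a six-layer raster — five co-registered reflectance bands (blue,
green, red, red edge, NIR; central wavelengths ~446/548/650/720/840 nm) plus
a canopy-height layer — together with a plot map (the designed grid of
replicate × row × column positions, with never-sown blanks flagged) and, for
training, per-plot fresh biomass in kg labeled by harvest month and
replicate. The canopy-height layer is the photogrammetric surface model
minus the terrain model, converted to cm and clipped below at zero (negative
differences over bare soil are reconstruction noise, not canopy).
Reflectance calibration is a single multiplicative gain per band anchored to
a reference panel of known nominal reflectance (default 60%); no offset term
is fitted because the panel provides one constraint per band.

## Synthetic field generator

The simulator is the package's substitute for field data and defines the
conditions under which the pipeline is validated.

**Layout.** Three replicates of 23 rows × 12 columns; plots 1.52 m × 0.30 m,
row gap 0.91 m, column gap 0.30 m, ground sampling distance 0.98 cm/pixel.
The default blank positions leave 269/269/270 sown plots per replicate (808
total), matching the per-replicate plot counts of the reference trial; blank
layout is configurable because real designs vary.

**Month presets.** Plot-level means and sds of biomass (kg), vegetative area
(pixels), canopy height (cm), NDVI, NDRE and NGRDI for the May, July and
September harvests, averaged over replicates. September's canopy is sparse:
mean biomass 0.37 kg versus 3.88 kg in May.

**Generative model.** Each sown plot draws a latent vigor `v ~ N(0,1)`. The
standardized features load on `v` through a single-factor model: area = v,
height/NGRDI/NDRE/NDVI = ρ·v + √(1−ρ²)·ε with ρ = 0.5/0.6/0.3/0.6. These
loadings were chosen once to bracket the 0.3–0.7 inter-feature correlations
observed in the field data without asserting exact values. Standardized
biomass is

```
biomass* = 0.70·area* + 0.07·height* + 0.18·ngrdi* + 0.07·ndre* + N(0, σ²)
```

with σ = 0.55 by default. Under the factor model the signal variance is
βᵀΣβ ≈ 0.775, so σ = 0.55 implies a generative R² of
0.775/(0.775+0.3025) ≈ 0.72 — the accuracy regime the method operates in on
real fields. `noise_sd_for_r2` inverts this relation exactly.

Features and biomass are then de-standardized to the month preset moments.
Biomass is truncated at 0 kg (relevant only in September, where ~3% of
draws would be negative; the standardized generative columns are kept
untruncated alongside). Area is expressed as a canopy-pixel count and
clipped to the plot-rectangle capacity so the area fraction stays in (0, 1];
with the May preset roughly a quarter of plots saturate at full plot cover,
a deliberate consequence of keeping the preset moments and the physical plot
size simultaneously.

**Rendering.** Each sown plot is painted as a centred
rectangle-with-eroded-corners: plot-rectangle pixels are ranked by a
superellipse distance ((|dy|/h)⁴+(|dx|/w)⁴) and the first `area_px` pixels
become canopy. Canopy reflectances are solved per plot from the true
NDVI/NDRE/NGRDI at fixed canopy NIR (0.35) and blue (0.05); soil pixels get
a fixed soil spectrum (blue .06, green .10, red .12, red edge .18, NIR .22;
soil NDVI ≈ 0.29). The height layer carries the true height on canopy
pixels and 0 elsewhere. Optional additive Gaussian pixel noise models sensor
noise; there is no radiative transfer, illumination gradient or shadow
simulation, and rendered fields contain exactly two pixel populations
(canopy and soil). Consequences: pipeline runs on rendered fields use k = 2
clusters (the third class in real imagery — shade, drainage pipes — has no
synthetic counterpart), and because the September preset's canopy NDVI
(~0.28) sits below the default soil NDVI, rendered-field validation uses the
May/July presets. Passing tests on rendered fields therefore demonstrate the
mechanics of segmentation and extraction, not robustness to shadows,
mixed-pixel borders, or weed cover.

## Segmentation

1. **Pixel classification.** k-means (k-means++ initialisation, fixed seed,
   single initialisation, tol 1e-4, ≤300 iterations) in the red × NIR
   channel space, k = 3 by default for real imagery.
2. **Vegetation class.** Cluster labels are arbitrary, so the vegetation
   class is the one with the highest mean NDVI — the same criterion that
   defines vegetative area. A tie within 1e-9 is reported as ambiguous; a
   best class with negative mean NDVI triggers a "no vegetation" warning.
3. **Grid detection.** Vegetation counts are projected onto rows and
   columns; the profile is cropped to its support (making detection
   invariant to soil padding), smoothed with a moving average of 0.25× the
   plot pitch (from the expected grid if given, else the dominant FFT period
   of the profile), and cut at the minima between consecutive peaks.
   Detected counts are checked against the expected design when provided.
4. **Boundary refinement.** Plots that straight gridlines cannot separate
   are handled here: each cell's search window extends to the midlines
   toward neighbouring cells, the vegetation inside is split into connected
   components, and the component nearest the cell centre becomes the plot's
   mask. Windows partition the raster, so no pixel is assigned to two plots;
   blank plots always receive empty masks. This refinement rule is a
   documented stand-in validated against synthetic truth only.

## Features

Per plot: area (vegetation pixel count), height (mean of the height layer
over vegetation pixels — vegetation-only, not whole-cell), volume
(area × height), and 19 vegetation indices computed from the plot-mean band
reflectances (VI-of-means; pixel-wise averaging is available but off by
default). The registry fixes the eleven indices the modeling narrative uses
(NDVI, NDRE, NGRDI, SR = NIR/RE, CI_RedEdge = NIR/RE − 1, CI_Green, GRVI,
EVI, RVI, MCARI, EXG) plus eight conventional fill-ins (GNDVI, SAVI, OSAVI,
MSAVI, EVI2, EXR, EXGR, TVI) to reach the 22-feature contract; it is
user-extensible, and the selection procedure is designed not to depend on
the fill-ins. NDRE, SR and CI_RedEdge are monotone transforms of one ratio
and always rank plots identically. Zero denominators yield NaN markers, not
exceptions; empty plots report area 0 and NaN indices and are excluded from
standardization groups by NaN propagation.

## Modeling

Standardization is z-scoring per month × replicate with sample sd (n−1);
groups need ≥3 plots and nonzero variance. Feature correlations are
pairwise-complete Pearson; two-way clustering is complete-linkage Euclidean
on the standardized matrix. Feature importance is the leave-one-feature-out
increase in residual sum of squares against the full 22-feature OLS fit
(non-negative by nesting; collinear designs fall back to pseudo-inverse
fits with a warning — exact duplicates then each show ~zero contribution
despite being jointly informative, which is a property of the measure, not a
bug).

Selection: (1) strongest |R| with biomass (area); (2) height whenever the
runner-up is the composite volume; (3) exclude NDVI (it defines area),
features with |R| to NDVI above 0.9 in either direction, and features with
|R| to biomass below 0.3 — the 0.9/0.3 thresholds are explicit configuration
because the underlying field procedure was narrative rather than numeric;
(4) cut the remaining candidates into two clusters and take each cluster's
strongest biomass correlate. On simulator defaults this returns area,
height, one of the NDRE/SR/CI_RedEdge rank-twins, and NGRDI.

The final model is OLS on the standardized scale. Two published coefficient
presets are shipped: `final` (0.70/0.07/0.18/0.07 on area/height/NGRDI/NDRE,
trained with one rain-affected month × replicate group removed — `fit_ols`
supports the same caller-flagged group exclusion) and `full`
(0.66/0.07/0.15/0.04, all training data). R² is the squared Pearson
correlation of observed vs predicted (affine-invariant; `1 − SSE/SST`
offered as an option), RMSE is in the units of its inputs, and back-transform
to kg uses caller-supplied group means/sds.

## Validation

Threefold cross-validation under three schemes: temporal (folds = months),
spatial (folds = replicates), mixed (uniform random thirds, default 100
iterations, all randomness from one master seed via a seed sequence).
Accuracy is reported as the mean fold R² and as the median over
month × replicate cell R² values; cells with fewer than 3 held-out rows are
marked undefined. The default standardization mode refits group statistics
inside each training fold and standardizes held-out features with training
stats where the group was seen, else with the held-out group's own feature
statistics; held-out biomass statistics are never used, since per-cell
squared-Pearson R² is invariant to the per-group affine scaling of observed
biomass. The `pre` mode accepts a globally pre-standardized table, which
reproduces the common standardize-before-CV workflow (slightly leaky) and is
also the natural mode for the generator's standardized output. Temporal and
spatial schemes are deterministic; mixed results are bit-for-bit
reproducible under a fixed seed.

Independent-field validation applies a frozen model to a second field:
features are standardized within the test field's own groups, predictions
are compared per replicate (R², Spearman, RMSE), and a leakage guard rejects
any overlap between training and test plot keys (keys include an optional
field tag so same-position plots in different fields are distinct).

## Numerical conventions and defaults

- Pixel coordinates 0-based (row, col), row 0 at the raster top; all boxes
  and masks half-open.
- Heights in cm, biomass in kg, reflectances as fractions; rasters stored as
  float32 multi-layer TIFF with a JSON description tag (layer names, pixel
  size); GeoTIFF georeferencing is carried if present, never required.
- k-means uses a caller-supplied seed; constant images are rejected rather
  than clustered.
- Sample sd (n−1) everywhere.
- Problem sizes used in the shipped validation: full-design simulations
  (n = 2424 plot-month rows) for coefficient recovery and cross-validation
  calibration; one noiseless rendered replicate (23 × 12, ~2930 × 2330 px)
  for the imaging chain.

## Known limitations

- The simulator encodes month-level moments and a single-factor correlation
  structure only; real per-plot spatial autocorrelation, irrigation
  artifacts and measurement error structure are not modeled.
- Rendered fields have two pixel classes; the three-class clustering default
  is exercised on constructed three-class images in the tests, not on
  rendered fields.
- September-preset fields cannot be segmented by the NDVI criterion against
  the default soil spectrum (canopy NDVI below soil NDVI); use a darker soil
  or another month for rendered-field work.
- The boundary-refinement rule is a plausible stand-in for established
  plot-segmentation tools, validated only against synthetic truth.
- Biomass truncation at 0 kg slightly biases September kg-scale moments; the
  standardized generative columns are unaffected.
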