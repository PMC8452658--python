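# Methods

## The retrieval model and its two printed forms

The core model treats canopy NDVI as saturating exponentially with leaf
area. The package uses the pair

```
forward:  NDVI(LAI) = NDVI_inf + (NDVI_bs − NDVI_inf) · exp(−LAI / K_ndvi)
inverse:  LAI(NDVI) = K_ndvi · ln((NDVI_inf − NDVI_bs)/(NDVI_inf − NDVI))
```

which are exact inverses of each other. Two conventions for `K_ndvi` exist
in the literature on this model family: as a multiplier inside the
exponential (`exp(−K·LAI)`) or as the multiplier of the logarithm in the
inverse. The two are mutually inconsistent unless `K` is reinterpreted as
its reciprocal. The published per-stage equations this package renders and
audits (`LAI = 1.58*ln(0.78/(0.93−NDVI))` style) use `K` on the logarithm,
so that convention is canonical here and the forward model carries
`exp(−LAI/K)`. This choice is deliberate and documented rather than
silently patched; all internal round-trip guarantees depend on it.

Inversion clamps: NDVI at or below `NDVI_bs` maps to LAI 0 (bare soil);
NDVI within `saturation_margin` (default 0.001) of `NDVI_inf` is evaluated
at the margin so the logarithm stays finite. The margin bounds retrievable
LAI at `K·ln(amplitude/margin)` (≈ 10.5 for the worked-example parameters),
beyond any crop canopy of interest.

## Fitting and LOOCV selection

Parameters are estimated by bounded nonlinear least squares **in NDVI
space** — residuals are `NDVI_obs − NDVI(LAI_obs)` — because the bounds are
stated for the NDVI-space parameters and the observation noise enters
through the vegetation index. Bounds default to `NDVI_inf ∈ [0.91, 0.97]`,
`NDVI_bs ∈ [0.01, 0.18]`, `K ∈ [1.3, 1.8]` and are configurable. The
optimizer is scipy's trust-region-reflective least squares with a
deterministic multi-start (the eight corners of the bound box plus its
centre), which removes any dependence on a single starting point; with 22
points and 3 parameters each fit is milliseconds.

Per growth stage, leave-one-out cross-validation refits once per held-out
sample (n fits on n − 1 points). Every fold's parameter set is then scored
by the RMSE of its **inverted** LAI predictions against all n samples, and
the lowest-RMSE candidate is selected; ties break toward the lowest fold
index (an arbitrary but deterministic rule). The selected model records
RMSE, RRMSE = RMSE / mean(observed LAI), and R² = squared Pearson
correlation of predicted vs observed LAI. RRMSE's denominator and the
Pearson-form R² are both conventions chosen here; the packaged per-map
statistics are consistent with a per-stage-constant RRMSE (the
uncertainty/mean ratio of the four same-stage Beijing rows agrees within
0.003), which supports this reading. A constant prediction series has no
defined correlation; R² is then reported as 0 with an explicit degeneracy
flag rather than NaN.

## Field LAI

`SLW = (DW)₀/A₀` and `LAI = DW/(SLW·A_s)` with weights in grams and areas
in cm²; `A_s` defaults to 10000 cm² (the 1 m × 1 m plot) and is overridable
per row. The combined form `LAI = DW·A₀/((DW)₀·A_s)` is scale-invariant in
the weights, which the tests assert. Scene-to-campaign matching accepts the
cloud-free acquisition nearest in time within ±7 days, ties toward the
earlier scene.

## Grids, aggregation, windows

Grids are planar single-band rasters: 0-based row/col, row-major, origin at
the top-left corner, square pixels, half-open windows. GeoTIFF I/O writes
float32 with the ModelPixelScale, ModelTiepoint and GDAL nodata tags.
Block aggregation requires exact divisibility (the synthetic world uses an
integer fine-to-coarse factor, default 10, i.e. 30 m → 300 m); partial-pixel
area weighting for non-integer resolution ratios is out of scope. Within a
block, the mean is over valid cells only — a block is nodata only when all
its cells are; this matches workflows restricted to cloud-free imagery
where missing data are rare. A window's pixel footprint places the pixel
containing the centre point at index (n/2, n/2); windows that cross the
grid edge are refused outright rather than truncated, so every reference
map covers its full stated footprint.

## Radiometric normalization

The fine band is aggregated to the coarse reference sensor's grid and
`coarse = slope·fine + intercept` is fitted by OLS over all valid pairs.
Regression direction (coarse on fine, applied forward to the fine pixels)
puts the corrected fine band in the coarse sensor's radiometric units,
which is the point of the exercise. The regression is used only when the
pairs' squared Pearson correlation strictly exceeds the gate (default
0.75); otherwise the band is rescaled by mean(coarse)/mean(fine), which
moves its mean onto the reference mean. A zero-variance fine band forces
ratio mode (the regression is singular). Outputs clip to physical
reflectance [0, 1].

## Upscaling and the scale effect

U1 inverts NDVI per fine pixel and block-averages the LAI; U2 block-averages
the bands, computes coarse NDVI, and inverts once. All pixels in a block
participate in both routes (masking is a reporting choice, not a retrieval
step). The difference U1 − U2 is the scale effect; its sign convention is
fixed by the packaged statistics rows (U1 − U2, e.g. 0.439 − 0.422 =
+0.017). When every pixel in a block shares the same total brightness
(red + nir), block-mean NDVI equals the NDVI of the block means and the
convexity of the inverse gives U1 ≥ U2 per block (Jensen); with unequal
brightness the band-averaging step reweights NDVI toward brighter pixels,
which is why bright-soil mixtures bias the average-first route low.

## Reference maps and their statistics

A candidate 3 km × 3 km window becomes a reference map only if its cropland
fraction **strictly** exceeds the threshold (default 0.75); rejections are
returned as machine-readable records (reason plus measured cover) so batch
runs can account for them. Each map's row holds: mean fine-resolution (U1)
LAI; uncertainty = mean LAI × stage RRMSE; the population (divide-by-N)
standard deviation of the fine LAI as the heterogeneity measure (at 10⁴
pixels per window the sample/population distinction is far below the
3-decimal reporting precision); the U2 mean; and the scaling difference.
Per-area summaries report the min/max of per-map mean LAI and arithmetic
means of the other columns, rounded to 3 decimals.

The packaged per-map statistics tables (80 rows over four study areas) are
shipped as CSV fixtures with the standard column headers, along with the
20 per-stage equation coefficients. Two known printed-precision artifacts
in these tables: the Beijing standard-deviation column averages to 0.723
while the corresponding prose value is 0.720, and one stage equation's
amplitude implies a bare-soil NDVI of 0.0095, marginally below the 0.01
fitting bound; the bounds audit therefore allows ±0.005 on the
amplitude-implied `NDVI_bs`.

## Product validation

Three comparison modes: U1 (one pair per map — window mean of the product
vs the map's fine-resolution mean LAI), U2 (one pair per coarse pixel vs
the average-first reference, which removes the scale effect from the
comparison), and direct (product pixel containing each field plot vs the
plot LAI). Relative bias is computed from pooled means,
`(mean_product − mean_reference)/mean_reference`, reported in percent —
not the mean of per-pair ratios — and the "All" row pools pairs across
areas rather than averaging area rows. A product that is biased low
agrees better with the U2 reference than with the U1 reference on
heterogeneous bright-soil scenes, because the U2 reference carries the
same average-first depression the coarse retrieval does; the tests assert
this ordering (and the direct mode's larger RMSE) as orderings, not as
specific values, since the specific published product scores depend on
external data.

## The synthetic scene generator

The generator's role is to produce inputs with exactly the statistical
structure the analysis assumes, so every claim the tests make is a claim
about the method, not about the data. It emulates: a block mosaic of square
farm fields (default 10-pixel blocks on a 100 × 100, 30 m grid) with an
exact count of cropland blocks matching the target crop fraction; one
stage-like LAI per field drawn uniformly from `lai_range` (default
0.2–4.0 m²/m²) with ±2 % within-field jitter; bright (red + nir ≈ 0.6) or
dark (≈ 0.2) bare soil, linearly interpolated toward a fixed canopy
brightness (0.45) as LAI approaches full cover (3.0); additive Gaussian
NDVI noise (default sd 0.01); an affinely distorted coarse reference
sensor; a coarse product equal to aggregated true LAI times (1 + bias)
plus optional noise; and destructive plots whose synthesized leaf weights
(SLW uniform in 0.004–0.010 g/cm², a plausible wheat range) invert exactly
to the pixel's true LAI. Each stage draws from its own seeded stream
(seed + fixed per-stage offset), so stages are independently reproducible.

What it does **not** emulate: radiative-transfer realism, BRDF and
view-angle effects, clouds, topography, registration error, within-pixel
crop mixtures, or phenology. Passing tests therefore demonstrate the
correctness and internal consistency of the estimators and the direction
of the scale effect — not the accuracy any particular sensor pair would
achieve on real landscapes.

## Problem sizes and numerics

Default desk-scale sizes: 100 × 100 fine pixels per scene (60 × 60 for the
multi-seed scale-effect contrasts), coarse factor 10, 22 plots per stage,
100 replicates for parameter-recovery medians, 20 scene pairs for the
bright/dark contrast. These sizes give stable statistics while keeping the
full suite and the reproduction script to seconds. Optimizer tolerances are
set tight (1e−14) so the multi-start fits are reproducible to well below
any asserted tolerance; float comparisons in grid code use exact nodata
sentinels with `isclose` matching on read-back.

## Known limitations

- Aggregation handles only integer resolution ratios; real cross-sensor
  work needs reprojection and area weighting this package does not attempt.
- The radiometric normalization is a global affine per band; no
  pseudo-invariant-feature selection or robust regression.
- The LOOCV selection assumes one model per growth stage and site; no
  pooling across stages.
- The product simulator represents a coarse product as rescaled aggregated
  truth; it does not emulate a LUT-based radiative-transfer retrieval.
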