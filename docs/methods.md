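# Methods

## The model

The package implements classical AHP-weighted suitability analysis. A crop's
requirements are expressed twice: *between* criteria, as a pairwise
comparison matrix over the nine environmental criteria (rainfall,
temperature, soil drainage, depth, texture, slope, elevation, soil organic
carbon, pH), and *within* each criterion, as ordered subclasses (value bins
or category groups) with their own weights. The cellwise suitability index
is the weighted overlay S = Σᵢ Wᵢ·w_ik, a number in (0, 1) that is ordinal,
not physical: it ranks land, and its observed range is what gets split into
the S1/S2/S3/N legend.

Assumptions worth stating explicitly:

- **Co-registration is a precondition, not a service.** All layers must
  share shape and geotransform; the pipeline checks and fails loudly rather
  than resampling silently, because implicit resampling of categorical soil
  layers is a classic source of irreproducible maps.
- **Additivity.** Weighted overlay assumes criteria contribute
  independently and compensate linearly; there is no interaction term (for
  example, high rainfall cannot rescue unsuitable drainage beyond its fixed
  weight).
- **Expert weights are data.** The judgment matrices are inputs carrying
  their own quality statistic (CR); the package refuses to overlay with an
  inconsistent matrix (CR ≥ 0.1) unless forced, and a forced run is flagged
  in the manifest.

## AHP numerics

Weights come from column normalization: divide each column of the matrix by
its column sum and average each row of the normalized matrix; the result is
renormalized to sum to 1 exactly (the derivation is algebraically
normalized already; the extra division removes float drift). This
approximation tracks the principal eigenvector closely on near-consistent
matrices — the test suite requires max-component agreement within 0.02
against power iteration whenever CR < 0.1 — and is exact when the matrix is
perfectly consistent (a_ij = w_i/w_j).

λ_max is estimated from the consistency vector (A·w)ᵢ/wᵢ. Three estimators
are exposed:

- `"max"` (default): the maximum component. This is the convention used by
  common spreadsheet AHP audits, and it is the package's reporting
  convention for consistency footers.
- `"mean"`: the mean component, Saaty's textbook estimate.
- `"eigen"`: the exact principal eigenvalue from a dense solver.

All three coincide at n for a consistent matrix and satisfy λ_max ≥ n on
positive reciprocal matrices; `max` ≥ `mean` ≥ exact-eigenvector bounds make
`max` the most conservative choice for gating (it never under-reports
inconsistency). CR for n ≤ 2 is defined as 0, since RI = 0 and a 2×2
reciprocal matrix is always consistent.

Reciprocity is validated with a 5 % relative tolerance so matrices entered
with 2-decimal reciprocals (0.13 for 1/8, 0.11 for 1/9) validate; entries
are otherwise taken exactly as given. Matrix CSVs may mark the lower
triangle as derived (`lower="auto"`), in which case the upper triangle is
authoritative and reciprocals are filled exactly.

## Classification schemes

Each packaged scheme stores its bins, subclass weights, and the consistency
footer (n, λ_max, CI, RI, CR) of the subclass judgment matrix behind it; the
footers are re-derived from λ_max by the same CI/CR arithmetic as the
criterion matrices and verified in tests (CI to within 6×10⁻⁴, CR to within
10⁻³ of the recorded 3-decimal values — 1 ulp of slack because a rounded CI
divided by RI and an unrounded one can disagree in the last printed digit).

Interval bins are lower-inclusive, upper-exclusive, with the extreme bins
absorbing their boundaries (the topmost finite edge is inclusive, so pH 8.5
falls in 7.5–8.5). Values outside a scheme's declared domain raise an error
rather than clamp: the schemes were built to span the region a study
observes, and a value outside them means the inputs are wrong, not the bin
edges. Grouped bins (the coconut pH scheme maps two disjoint intervals to
one suitability group) repeat a label and weight across bins; weight-sum
validation (1 ± 0.02, rounding slack for 2-decimal weights) is over unique
labels. One packaged quirk kept as recorded: the rice depth scheme assigns
0.28 to both of its two deepest classes.

Soil pre-processing: 0–5 cm and 5–15 cm layers combine as
(5·v₀₋₅ + 10·v₅₋₁₅)/15; sand/silt/clay fractions (renormalized when within
100 ± 1) are classed by the USDA texture-triangle flowchart, evaluated as a
first-match cascade that is exhaustive over the simplex (property-tested on
a 2 % sweep); the 12 USDA classes then collapse into crop-specific groups
(rice: clayey / loam / sandy loam / loamy sand / sand; coconut: loam /
"SL, SiC, Si" / "S, C, LS").

## Climate preparation

Monthly climatology is a per-month, per-cell mean across years; the rice
temperature criterion uses the June–September growing-season mean, coconut
the annual mean; annual precipitation is the 12-month sum. Nodata in any
contributing month propagates.

IDW interpolation uses the k = 12 nearest samples by default (configurable,
`all` allowed), weight d⁻ᵖ, with an exact-hit short-circuit at zero
distance. The power p is chosen by bounded scalar minimization (Brent-style,
default bounds [0.5, 20]) of the leave-one-out RMSE computed with the same
IDW implementation. LOO-RMSE is a deliberate choice — the objective is not
prescribed by the workflow this mirrors, and cross-validated prediction
error is the standard way to pick p. The objective can be multimodal in
principle; the test suite checks the returned power against a 0.01-step grid
scan and against random probes.

## Classification, masking, areas

Equal-interval breaks use the observed (non-nodata) index min/max, not the
theoretical bounds Σ Wᵢ·min_k w_ik … Σ Wᵢ·max_k w_ik — observed-range
splits are what produce comparable before/after-masking tables. Values
exactly on an interior break go to the upper (more suitable) class; the
maximum lands in S1; a constant index is a degenerate-classification error
rather than an arbitrary single class. The pipeline order is score →
classify → mask, so the class legend is fixed before non-cropland cells are
recoded; masking conserves total cell count, and per-class areas can only
shrink. Areas are count × cellsize²/10⁴ hectares; every legend class gets a
row even at zero.

## Validation

Pseudo-absences are sampled uniformly without replacement over eligible
cells — excluding S1, nodata and (by default) masked non-cropland, so
absences stay comparable to mapped suitability; `allow_noncropland=True`
restores the literal "anywhere outside highly-suitable" rule. Points sit at
cell centers, at most one per cell, so coordinates never duplicate.
Extraction follows the half-open pixel convention [x, x+Δ) × (y−Δ, y];
points on nodata are dropped with a logged count. AUROC uses midrank tie
handling (the Mann–Whitney convention); the test oracle is exhaustive pair
counting, and invariance under strictly increasing score transforms is
property-tested. Pearson correlation of predicted vs observed per-district
areas is provided for acreage cross-checks (≥ 3 districts, non-zero
variance required).

## Synthetic landscape

The generator emulates the *statistical structure* the analysis assumes, at
desk scale: smoothed-white-noise random fields (Gaussian filter, default
correlation length 8 cells) for soil and climate; a DEM rescaled to
[−5 m, relief] with a cubic skew and a low western (coastal) edge, default
relief 1200 m on a 64×64 grid of 250 m cells; temperature as a seasonal
cycle minus a lapse of 0.65 °C per 100 m elevation plus smooth noise;
rainfall as an annual field (default 1300 mm at the coast, +40 mm/km
inland, sd 180 mm, floor 350 mm) split by monsoon-heavy monthly fractions;
sand/silt/clay via a softmax of smooth fields (exactly 100 % everywhere);
depth, drainage and 8-class land cover by rank-quantile thresholding of
smooth latent fields at configured proportions (exact to discretization,
hence well within ±5 points). Slope is Horn's 3×3 percent-rise stencil; the
odd-reflection padding makes edge cells exact one-sided differences for a
planar surface. Generated ranges are clipped to the packaged scheme domains
(pH 3.5–8.5, SOC 0.05–3 %, coconut annual temperature below 29 °C) so
reclassification never faults. One global seed drives named per-layer
substreams (seed, CRC32 of the layer name), so layers are independently
reproducible.

Occurrences: n presence cells are drawn without replacement with sampling
weight ∝ logistic(a + b·z), where z is the suitability index standardized
to zero mean and unit sd across valid cells — so b reads as log-odds per
index standard deviation, the conventional logistic-regression scale. The
default intercept a = −14 keeps a + b·z below zero for the default b = 10,
where the logistic is effectively an exponential tilt exp(b·z) and the
planted signal scales cleanly with b; large positive logits would saturate
the weights and flatten the signal. b = 0 yields uniform presence
locations. Weights are computed in log-space so strongly negative logits
stay proportional instead of underflowing.

What passing tests on this landscape do *not* show: real soil maps have
survey-polygon artifacts, not smooth latent fields; real rainfall and
temperature have topographic and coastal structure far richer than a linear
gradient plus lapse; real occurrence records carry sampling bias that the
logistic-in-suitability model deliberately lacks. Recovery results (AUROC
≥ 0.9 at b = 10; AUROC within 0.08 of 0.5 at b = 0 across 20 seeds)
validate the pipeline's machinery, not any real-world map accuracy.

## Problem sizes and runtime

The default test landscape is 64×64 cells (409.6 km² at 250 m) — large
enough for stable class areas and 200/200-point validation, small enough
that the full suite runs in well under a minute. IDW oracle checks use a few
dozen scattered samples; the AHP property suites draw ~100 random
reciprocal matrices of orders 3–9.

## Known limitations

- Raster I/O is ESRI ASCII grid only (plus JSON legend sidecars); there is
  no GeoTIFF reader/writer and no reprojection — grids are trusted to be in
  a common projected coordinate system in meters.
- The equal-interval legend is fixed at 4 classes (S1/S2/S3/N).
- Group-AHP aggregation, fuzzy AHP and interactive judgment elicitation are
  out of scope; subclass judgment matrices are represented only by their
  resulting weights and consistency footers.
- The index is ordinal; comparing index values across crops or across
  scheme versions is not meaningful beyond rank.
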