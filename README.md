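# cropsuit

Multi-criteria crop-suitability mapping for land-evaluation studies, built
around the Analytic Hierarchy Process (AHP) and GIS-style weighted overlay.
It is aimed at agro-ecologists and land-use planners who combine expert
judgment with gridded environmental layers (terrain, soil, climate, land
cover) to map where a crop can grow — and who need the weighting, the
consistency audit, the classification, and the validation to be reproducible
code rather than spreadsheet and desktop-GIS clicks.

## What it computes

**AHP weights with a consistency gate.** Expert judgments enter as an n×n
positive reciprocal pairwise comparison matrix *A* on Saaty's 1/9…9 scale.
Criterion weights are derived by column normalization (divide each column by
its sum, average each row). Consistency is audited through the principal
eigenvalue estimate λ_max of the consistency vector (A·w)ᵢ/wᵢ and

    CI = (λ_max − n)/(n − 1),    CR = CI/RI(n),

with RI the tabulated random consistency index. Matrices with CR ≥ 0.1 are
refused downstream (overridable with an explicit force flag). Three λ_max
estimators are exposed: the component maximum (default, the spreadsheet-AHP
convention this package standardizes on), the component mean (Saaty's
classical estimate), and the exact principal eigenvalue.

**Weighted-overlay suitability index.** Each criterion layer is reclassified
through packaged subclass schemes (bins or category groups, each carrying an
AHP subclass weight w_ik and its own consistency footer), and cells are
scored

    S = Σ_i W_i · w_ik(cell),

then split into S1 (highly), S2 (moderately), S3 (marginally) and N (not
suitable) at equal intervals of the observed index range. An 8-class
land-cover layer masks non-cropland (water, trees, built area, snow/ice) and
class areas are tabulated in hectares. Ready-made schemes and judgment
matrices are packaged for two coastal crops, rice and coconut, including the
soil pre-processing they assume (depth-weighted 0–15 cm averaging, USDA
texture-triangle classing, crop-specific texture grouping) and the climate
aggregation (monthly climatology, Jun–Sep growing-season vs annual means,
annual precipitation, IDW downscaling with leave-one-out-optimized power).

**Presence/absence validation.** Suitability maps are validated against
occurrence points: pseudo-absences are sampled uniformly outside the S1
class (and outside masked non-cropland), index scores are extracted at all
points, and the area under the ROC curve is reported with the usual reading
(> 0.9 very high, 0.7–0.9 high, < 0.7 low accuracy).

**Synthetic landscape.** A seeded generator produces a miniature coastal
landscape — smooth DEM with derived percent-rise slope, autocorrelated soil
and climate fields, categorical depth/drainage/land-cover layers, and
occurrence points whose probability increases with true suitability — so the
entire pipeline runs and is tested without any external data.

## Worked example

```sh
$ suit weights --crop rice
rainfall                   0.2903
temperature                0.0259
drainage                   0.2468
depth                      0.1120
texture                    0.1556
slope                      0.0576
elevation                  0.0576
soc                        0.0365
ph                         0.0177
n = 9
lambda_max = 9.9126  [max]
CI = 0.1141   RI = 1.46   CR = 0.0781  -> accepted (CR < 0.1)
```

Rainfall (0.29) and soil drainage (0.25) dominate the rice decision; the
consistency ratio 0.0781 is below 0.1, so the judgments are coherent enough
to use. Then simulate a landscape, run the full pipeline, and validate:

```sh
$ suit simulate --out fixtures/ --seed 7 --size 64 --occurrences 200
$ suit run --layers fixtures/ --crop rice --out run/
CR = 0.0781 (accepted)
       class  area_ha  area_pct
          S1  1131.25  4.418945
          S2  8956.25 34.985352
          S3  4950.00 19.335938
           N  1600.00  6.250000
non-cropland  8962.50 35.009766
wrote run/manifest.json

$ suit validate --index run/index.asc --classes run/masked_classes.asc \
      --presences fixtures/occurrences.csv --seed 42
AUROC = 0.987 (very high accuracy; 200 presences, 200 absences)
```

The area table reads: of this 64×64-cell landscape (6.25 ha per 250 m cell),
4.4 % is highly suitable cropland for rice after masking, 35 % of the area
is non-cropland, and percentages sum to 100. The AUROC of 0.987 says the
planted occurrence signal (presence probability increasing with true
suitability) is recovered almost perfectly. `run/manifest.json` records the
weights, the consistency audit, the class breaks and the package version for
the run.

The same is available as a library — `cropsuit.ahp.analyze`,
`cropsuit.pipeline.run_suitability`, `cropsuit.validation.auroc`, and so on;
see `docs/methods.md` for the model details and design choices.

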