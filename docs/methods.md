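# Methods

## The change-detection model

The pipeline assumes two co-registered 3-band (green/red/NIR) reflectance
rasters of the same pasture, acquired far enough apart in time for every
animal to have moved more than one body length, and close enough that
nothing else changed (same day; closed population; no machinery; similar
sun angle). Under those assumptions the only structured signal in the
absolute difference of the two first principal components is animal
movement, plus three error sources the accuracy framework is designed to
expose: residual mis-registration, shadow movement, and sensor noise.

### Per-image PCA

PCA is computed per image from the 3×3 **covariance** matrix of the band
values over valid (unmasked) pixels. Covariance rather than correlation:
the bands share one physical unit and rescaling would inflate the noisy
band's influence. Eigenvalues are clipped at zero and sorted descending;
PC1 is the centered band vector projected on the leading eigenvector.

The eigenvector sign is arbitrary per decomposition. An uncontrolled flip
between T1 and T2 would turn "no change" into "maximal change", so signs
are fixed deterministically: each eigenvector is oriented so the sum of
its three loadings is positive; if the sum is zero (to 1e-12), the first
nonzero loading is made positive. Two near-identical images then get
near-identical PC1 layers.

Clipping to the common extent happens **before** the decompositions so
both see the same spatial support. An all-constant image (covariance
trace at the round-off floor) is an error, not a silent zero map.

### Thresholding and polygonization

The spectral threshold interval is closed on both ends; the default upper
bound is +∞. The derived threshold (`suggest_threshold`) pools the
difference values in an odd window (default 3×3 pixels) around every
animal's T1 and T2 positions and returns a low percentile (default 0.05)
of the pooled sample. This formalizes an otherwise manual step while
keeping it overridable — the workflow is semi-automated by design, and a
manually chosen `t_low` is a first-class input.

Connected components use 8-connectivity by default (a compact blob plus
its point-spread halo can connect diagonally; 4-connectivity is available)
and polygon boundaries are unions of exact pixel squares — no smoothing or
simplification, so area is exactly `pixel_count × pixel_size²`. The area
filter keeps polygons with 0.99 m² ≤ area ≤ 10 m² inclusive; the published
removal rules are strict inequalities, so areas exactly on a bound stay.
At 0.25 m pixels the bounds fall between 15/16 pixels and 160/161 pixels.

### Matching and metrics

A polygon is eligible for an animal if it contains, or lies within
`r_match` (default 1.0 m, about half an adult cow's body length) of,
either the animal's T1 or T2 position; `t1`-only and `t2`-only modes are
selectable. Eligible pairs are assigned greedily by increasing
polygon-to-position distance, ties broken by animal id then polygon order,
so matching is deterministic. An animal is credited at most once; a
polygon absorbs at most two animals (a "dual" polygon — two individuals
close enough to difference as one blob). The second footprint of an
already-credited animal, if detected separately, counts as commission;
this keeps `known = credited + missed` exact.

P_correct counts credited **animals**, `(correct polygons + duals) /
known`; the polygon-counting variant is exposed separately as
`p_correct_polygon_form`. Percentages are kept unrounded internally;
display rounding is nearest integer, halves away from zero, and
multi-pasture means and sample SDs (n−1) are taken over the unrounded
values before rounding. With zero mapped polygons P_commiss is reported
as 0 with an explicit no-detections flag.

### Registration

Tie-point registration fits a first-order (6-parameter) affine transform
by least squares — the minimal model for rigid flight-line geometry;
higher orders could sit behind the same contract. RMSE is reported in
pixels (residual RMS in meters divided by the target pixel size).
Collinear or duplicate tie-point configurations (design-matrix rank < 3)
are rejected. Warping resamples bilinearly onto the target grid; an
output pixel whose bilinear stencil touches nodata or leaves the source
grid is nodata. The mis-registration report takes **absolute** per-axis
offsets of independent check features, with mean and sample SD; offsets
are magnitudes because they are compared against animal body length. The
CSV writer offers meters or centimeters.

## The synthetic pasture generator

The generator emulates what the method needs from real data, not what the
data looks like. Defaults (all overridable through `SceneConfig`):

| parameter | default | rationale |
|---|---|---|
| extent, pixel | 250 × 250 m, 0.25 m | ≈ 6.2 ha, the campaign's mean pasture |
| background mean (g, r, NIR) | 0.08, 0.10, 0.30 | autumn grassland reflectance |
| texture | Gaussian field, 2 m correlation, sd 0.01 | within-pasture grass variation |
| bare-soil patches | 40 ellipses, 2–20 m², Δ = (+0.02, +0.02, −0.15) | sparse/dense grassland mosaic; static between acquisitions |
| animals | ellipses 1.2–3.0 m², aspect 1.5–2.5, Δ = (−0.03, −0.04, −0.15) × jitter 0.8–1.2 | dark cattle/horses of mixed size and coat |
| movement | uniform 2–20 m, direction uniform, rejection at the fence | beyond one body length; preserves the distance distribution |
| shadows (off by default) | offsets (1.8, −2.2) m at T1 and (2.6, −3.0) m at T2, intensity 0.6 | sun movement between acquisitions |
| mis-registration | (0, 0) m | injected per experiment |
| point-spread blur | σ = 0.7 px | sensor/optics mixing at the pixel scale |
| noise | additive sd 0.003 per band per acquisition | sensor noise ≪ animal contrast |

One integer seed drives every draw; a multi-pasture suite derives scene
seeds as `base + index`. The soil patches matter: they cancel exactly
under perfect registration, but their sharp NIR edges are what a sub-meter
shift turns into false change — without them a smooth background would
make the mis-registration experiments vacuously clean.

What the generator does **not** model: BRDF and atmospheric effects,
animal shape beyond ellipses, herd behavior (animal placements are
independent), terrain, and vegetation growth between acquisitions.
Passing tests on these scenes therefore demonstrate the pipeline's
internal correctness and its qualitative error structure, not field
performance on arbitrary real imagery.

## Standardized experiments (`pasturediff.scenarios`)

**Clean recovery.** Uniform adult animals (2.2–2.8 m², aspect 1.8–2.2,
uniform contrast −0.05/−0.06/−0.20, blur σ = 0.5 px), no shadows, no
mis-registration, derived threshold at the 2nd percentile. The uniformity
is the point: the derived-threshold rule pools window samples across
animals, so the scene's weakest or smallest animal is always the one the
threshold cuts closest; size and contrast heterogeneity are themselves
confounders of the heuristic, and the clean condition removes them along
with the physical ones. Expected outcome: zero omission on essentially
every seed, and commission equal to the duplicate-footprint rate (~50%:
both of each animal's footprints are detected, one is credited).

**Error attribution.** The same pastures re-rendered with one confounder
at a time — the campaign-mean 1.06 m Y mis-registration, or shadows whose
offset differs between acquisitions — and analysed at a fixed spectral
threshold of 0.10 (about half the animal PC1 contrast, the kind of value
a human analyst separating animals from background would choose). A fixed
threshold is used for two reasons: cross-condition commission is only
comparable at a common threshold, and the blind window sampling of the
derived rule breaks down once the T2 footprints are displaced from the
recorded truth coordinates (a human analyst samples the blob they see,
not a coordinate). Expected outcome: commission rises sharply under
mis-registration (soil-patch edges difference into animal-sized strips)
and under shadows (shadow change polygons), while omission stays at zero.

Problem sizes: the standardized experiments use 20 seeds of 12-animal,
250 × 250 m pastures per condition; unit tests use 80 × 80 m scenes with
5 animals.

## Numerical conventions and degenerate inputs

- 0-based (row, col); north-up; pixel centers for point coordinates;
  half-open pixel footprints `[x, x+s) × (y−s, y]` (a point on an edge
  belongs to the higher column / higher-index row).
- Planar map coordinates in meters throughout; no projection machinery.
  Reflectance units need only be consistent within a run.
- Nodata is a boolean mask internally; the GeoTIFF sentinel (−9999) exists
  only at the file boundary. NaNs fold into the mask on construction.
- Grids must share a lattice to within 1e-6 m for clipping/differencing.
- Rasters are written float32 with fixed creation options, so identical
  images produce byte-identical files.
- Polygon extraction orders components by (min row, min col); matching
  breaks ties by animal id then polygon order — all outputs are diffable
  across runs.
- Degenerate inputs raise typed errors rather than degrade: all-masked
  images, < 4 valid pixels or constant bands for PCA, collinear tie
  points, truth positions with no unmasked window samples, inconsistent
  evaluation counts, detection probabilities outside (0, 1].

## Known limitations

- The derived spectral threshold assumes the truth coordinates coincide
  with the difference blobs; under large residual mis-registration it
  must be replaced by a manual threshold (the CLI exposes both).
- Commission can never fall below the duplicate-footprint rate when both
  acquisitions' footprints are detected; separating "second footprint of
  a counted animal" from genuine false positives would require track
  reasoning that the single-pair design does not support.
- The 0.99–10 m² area filter is calibrated for cattle/horse-sized animals
  at 0.25 m pixels; other species or resolutions need re-derived bounds.
- Scenes larger than memory are not tiled; pastures at the intended scale
  (tens of hectares) are far below that limit.
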