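# Methods

This package implements a complete desk-scale pipeline for mapping coastal
driftwood deposits from multispectral satellite imagery and analysing their
spatial distribution. Because the real inputs of such a study (commercial
nano-satellite scenes, aerial orthomosaics, land-cover and infrastructure
databases) are not redistributable, the pipeline is developed and validated
against a synthetic landscape generator with known ground truth. This note
describes each model, its assumptions, the parameters that matter, and what
passing the test suite does and does not demonstrate about real data.

## The synthetic landscape

All layers live in a single projected metric coordinate system. The
landscape is a coastal strip: sea below a straight shoreline, a sandy beach
band (default 150 m; 2 km in the macro study), vegetated uplands, vertical
river channels draining at configurable mouth positions, and a gentle DEM
(0.5 % slope plus smooth noise) that is zero over water.

**Deposit placement.** Each forested river mouth sources deposits whose
along-coast distance follows a two-component mixture calibrated so that the
marginal law is exactly Exponential(`decay_scale_km`, default 112 km) at
and beyond the cluster radius (15 km): with probability
`F(15) = 1 − exp(−15/112)` the distance is drawn from a short-scale
(5 km) truncated exponential — the dense delta/coastal cluster — and
otherwise as `15 km + Exp(112 km)`, which by memorylessness reproduces the
exponential tail exactly. This keeps the closed-form check
`P(d ≤ 200 km) = 1 − exp(−200/112) ≈ 0.832` valid while giving clusters a
realistic density contrast over the background coastline. The expected
deposit count per mouth is calibrated so the realized density inside the
cluster radius matches `cluster_density_per_km2` (default 0.85 km⁻², over a
coastal band one beach-width deep), scaled by the catchment's boreal forest
fraction — the generative counterpart of the analysis finding that
driftwood cover tracks catchment forest cover. The configured
`background_density_per_km2` (0.16) documents the intended contrast; the
realized background density follows from the exponential tail rather than
being controlled independently.

**Sizes and shapes.** Deposit areas are lognormal per setting with
(mean, sd) defaults of (1551, 5132) m² inside clusters, (1031, 2165) m²
background, and (1024, 2075) m² deltaic. Note these pairs imply nearly
identical lognormal *medians* (≈ 450 m²), so rank-based tests on synthetic
sizes are legitimately weak even though the mean ordering (cluster >
background) is reliably recovered. Shapes are a Bernoulli mixture of
shoreline-parallel ellipses with 3–6:1 aspect ("berms") and compact blobs
("mats"); the within-deposit texture of real wood is not modelled.
Individual logs (thin rectangles, lognormal mean 30 m²) can be added via
`log_fraction`; they are below the 3 m minimum mapping unit and only
resolve on the aerial grid, which is what drives the size-stratified
evaluation result.

**Remobilization.** With probability `1 − remobilization_prob` (default
0.75) a deposit persists through all years with identical geometry. A
transient deposit appears in a uniform-random strict subset of years with
freshly drawn geometry per year, so per-pixel multi-year fusion correctly
treats its occurrences as unrelated single-year detections.

**Rendering.** Per-year imagery is rendered as overlapping vertical scene
strips. Pixel values are per-class band means (B, G, R, NIR, reflectance
scale) plus Gaussian noise (sd 0.02); each scene carries multiplicative
gain (sd 0.05) and additive offset (sd 0.01) jitter per band, which is what
histogram matching must undo. Driftwood is separated from sand chiefly by
NIR (0.20 vs 0.30) with overlap under noise, so segmentation is learnable
but not trivial. The reference composite is the noiseless render
block-averaged to 30 m; the aerial render re-rasterizes the truth at
0.5 m. Rasterization uses the pixel-centre rule throughout, so interior
rings are honoured exactly and polygon area ≈ pixel count × pixel area up
to boundary effects.

What the generator does **not** emulate: clouds and shadows, sea ice,
mixed pixels (class transitions are hard), sensor PSF, within-deposit
reflectance texture, coastline curvature, and geolocation error. Passing
tests therefore demonstrates the correctness and internal consistency of
the pipeline's logic and statistics under the stated generative
assumptions — not field accuracy on real imagery.

## Compositing

Scenes are harmonized by monotone quantile mapping per band: each source
value's mid-rank quantile is mapped through the reference's empirical
inverse CDF at mid-rank positions, which makes matching a distribution to
itself a fixed point and the whole operation idempotent. Matched scenes
are merged on the tile grid taking the per-pixel medoid (the observation
minimizing summed Euclidean distance to the other valid observations)
across contributors — the medoid never invents spectra, and a single
contributor passes through unchanged. Elevation is appended as a fifth
band, bicubically resampled to the composite grid.

## Segmentation

The classifier is an encoder/decoder ("U"-shaped) fully convolutional
network implemented directly in numpy with hand-derived backward passes
(3×3 convolutions via nine shifted tensor contractions, batch
normalization, 2×2 max pooling, nearest-neighbour upsampling with skip
concatenation, a 1×1 sigmoid head, Adam). Encoder convolutions are dilated
(rate 2 by default), which widens the receptive field at constant parameter
count — asserted by test. Desk-scale defaults are 2 levels, 8 base
filters, 64 px patches (~30k parameters); depth, width, and patch size are
configuration.

The loss is the Tversky index complement with soft counts,
`1 − (TP + ε)/(TP + α·FP + β·FN + ε)`, defaulting to α = 0.3, β = 0.7:
false negatives cost more, which suits a target class occupying ~1–2 % of
pixels. α = β = 0.5 recovers the Dice loss exactly (property-tested), and
the ε = 1 smoothing makes the all-background/all-correct case a zero-loss
fixed point. Inputs are standardized per band using training-set moments
stored with the model.

Training areas are full-height vertical strips of the tile, split
60/20/20 by largest-remainder apportionment. Strips (rather than square
blocks) guarantee that every split contains all surface types; with block
splits a training set can miss open water entirely, and the network then
extrapolates arbitrarily over the sea. Training patches are drawn with a
50/50 balance of driftwood-containing and pure-background patches —
enough positives to drive the Tversky gradient, enough negatives to anchor
the beach and water classes. Augmentation (flips by default; the full
catalogue of crops, contrast/gamma, piecewise-affine, perspective,
normalization and blur is available) applies geometric transforms to image
and mask jointly (mask via nearest neighbour) and photometric transforms to
the image only. The best-validation-loss checkpoint is retained.

Inference tiles the composite with stride `patch − floor(0.02·patch)` (2 %
overlap), clamping the final tile to the boundary; a pixel is driftwood if
any contributing patch calls it driftwood at threshold 0.5 (the union
rule), and the probability raster keeps the per-pixel maximum for
diagnostics. Training labels can be bicubically upsampled (nearest for
masks) by `upsample_factor`; the desk default is 1 — at 3 m the synthetic
deposits span tens of pixels, and upsampling triples runtime for no
measurable gain on this generator (the full-scale value 3 remains
available).

## Fusion and filtering

Annual binary predictions are fused per pixel into a presence probability:
detections divided by years with a valid observation (never-observed
pixels are NaN). Deposits are extracted by a seeded dual threshold:
8-connected components of the probability ≥ 0.5 mask become deposits iff
they contain at least one pixel ≥ 0.6. With three years these thresholds
mean "shape grows over 2-of-3 pixels, seeded by 2-of-3 pixels"; with two
years, "seeded by 2-of-2, grown over 1-of-2" — verified by exhaustive
enumeration for 2–4 years. Components are vectorized as unions of pixel
squares, so areas are exact pixel counts × pixel area and interior rings
(holes) are counted exactly. Filters then remove deposits with water
coverage strictly above 20 % of their footprint (water mask: flagged water
in strictly more than 20 % of observations), deposits intersecting any
road or building feature, and deposits with more than five interior rings
(exactly five is kept); the removal log records the first failed rule.

A filter-cascade interaction worth knowing: if the classifier
over-predicts along the beach, separate deposits chain into one large
component that can touch water and be removed wholesale, collapsing
recovery. The strip-split and patch balance above exist to prevent this
failure mode.

## Spatial statistics

Deposits are aggregated to a hexagonal grid (pointy-top, incircle diameter
= cell size, default 10 km; "cell size" is interpreted as the incircle
diameter and exposed in config). Area is split among cells by geometric
intersection; counts are assigned to the centroid cell. Contiguity is the
six edge-sharing neighbours — on a hexagonal tessellation queen and rook
adjacency coincide — with row-standardized weights. The analysis frame is
restricted to cells intersecting the shoreline strip: open-sea and inland
cells carry no information about coastal deposits and only dilute
permutation inference.

Global Moran's I uses the standard cross-product form with a permutation
pseudo-p computed as (1 + exceedances)/(1 + permutations), 999 permutations
by default; its null mean is checked against −1/(n−1). Local Moran's I per
cell uses conditional permutation (the cell's own value held fixed,
neighbour values resampled from the remaining cells), one-sided pseudo-p in
the direction of the observed statistic, quadrant labels from the signs of
the centred value and its spatial lag, and hotspot clusters as contiguous
groups of significant high-high cells. At desk scale (~60 coastal cells)
the permutation floor of 1/1000 together with modest cell-level contrast
makes the strict operating point p < 0.002 rarely attainable; the macro
study reports that operating point faithfully (typically zero clusters)
alongside a 0.05-level diagnostic count. Detecting delta hotspots at
p < 0.002 requires the cell counts and contrast of a continental-scale
dataset.

Group comparisons use the Mann–Whitney U from midranks with exact
enumeration of rank assignments when C(n+m, n) is feasible and a tie- and
continuity-corrected normal approximation otherwise. Spearman's ρ is the
Pearson correlation of midranks with exact permutation p for n ≤ 8 and the
t approximation beyond.

**Bayesian estimation.** The two-group comparison keeps the robust
t-likelihood with per-group scales and a shared shifted-exponential prior
on the normality parameter ν, but places a Cauchy(0, 0.707) prior on the
*standardized* effect δ rather than independent broad priors on the group
means. The reason is calibration of the Bayes factor: under independent
very-broad mean priors the implied prior density of δ at zero is
essentially nil, so a Savage–Dickey ratio diverges even for null data.
With the Cauchy prior the Savage–Dickey ratio
BF₁₀ = p(δ=0)/p(δ=0 | data) is well defined (posterior density at zero via
Gaussian KDE of the MCMC draws), behaves correctly in both calibration
regimes, and the analytic two-sample JZS factor is computed alongside as
an independent cross-check. Sampling is an affine-invariant ensemble (16
walkers, 800 steps, 300 burn-in, seeded); acceptance fraction and a rough
effective sample size are reported, with a convergence flag. The 95 % HDI
(narrowest interval) is reported for the raw mean difference and — when
both groups are positive — for the log-ratio of group means, labelled
separately, since a difference-in-means HDI and a ratio HDI answer
different questions. Correlation evidence uses the rank-transformed
Pearson r with a uniform prior on ρ and a grid posterior under the
standard large-sample likelihood approximation; BF₁₀ is again
Savage–Dickey at ρ = 0.

**Coastal rules.** Deposits in catchments without forest cover are handed
to the forested catchment whose outlet is nearest along the coastline
(distances measured by projection onto the coastline); deposit-to-mouth
distances for the decay analysis are straight-line in the projected plane.
The cumulative-cover curve is the area-weighted empirical CDF of those
distances (step function, not interpolated), and the declining-cover
correlation is computed on area per equal-width distance bin versus bin
midpoint — equal-count bins would flatten the decay by construction.

## Evaluation

Mapped deposits are compared with an aerial-resolution reference by
aggregating both onto a square grid (512 m default, origin at the extent
corner): OLS of predicted on reference area per cell (free intercept by
default; the through-origin slope is also reported), r², and the overall
relative bias 100·(Σpred − Σref)/Σref. For size-stratified bias, reference
deposits are binned by area (edges 100 and 10 000 m²), each prediction's
area is credited to the reference deposit it overlaps most, unmatched
predictions are pooled as commission, and per-bin biases are reported with
each bin's share of reference area; the overall bias equals the
share-weighted bin combination by construction (tested). In this package
the reference segmentation is the simulator's year-0 truth rasterized at
aerial resolution — an oracle, standing in for a separately trained
aerial-imagery model; training a second network would exercise no new code
path while doubling the end-to-end runtime.

## Problem sizes and determinism

The desk pipeline runs on a 1536 m tile (512² px at 3 m, three years, two
scenes per year, ~60 deposits plus logs); the macro study is a 600 × 30 km
strip with five mouths (~1700 stable deposits) analysed at the vector
level; the decay closure uses a single mouth on a 2400 km strip with
12 000 deposits so that extent truncation of the exponential is
negligible. One global seed fans out to per-stage seeds by hashing the
stage name, so stages are independently reproducible; reruns with the same
configuration reproduce deposit geometry bit-for-bit. The numpy network
is fully deterministic given its seed.

## Known limitations

- The generator's spectral world is piecewise-constant with additive
  noise; real driftwood/sand confusion (the reason the original labelling
  needed log-structure checks) is far harder.
- Rank tests on synthetic deposit sizes are weak by construction (see
  above); significance levels for those comparisons are data-bound and
  not asserted by tests.
- LISA hotspots at p < 0.002 need more cells than a desk-scale strip
  provides.
- The BEST-style Bayes factor depends on a KDE estimate at a single point;
  for extreme separations it is reported as a large finite number rather
  than infinity, and the JZS analytic factor is the better-behaved
  cross-check there.
- Geodesic geometry, cloud masking, and cross-sensor harmonization
  coefficients are out of scope; all coordinates are planar metric.
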