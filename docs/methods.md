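# Methods

This note records what `standcount` computes, the assumptions behind it, and
the design choices made where more than one reasonable option existed.

## Working scale and geometry

All computation happens on a grid of 1 px = 1 cm.  Coordinates are `(x, y)`
in cm, origin at the top-left pixel corner, x rightward, y downward; pixel
`(i, j)` covers the half-open cell `[j, j+1) × [i, i+1)` cm, so its center
is `(j + 0.5, i + 0.5)`.  Every module shares this convention.

Scale normalization resamples RGB imagery bilinearly and masks by nearest
neighbour (masks must stay two-valued); output dimensions are
`round(dim × gsd / target)`.  When the ground sampling distance is unknown,
it is estimated from the crop row spacing: candidate across-row directions
are scanned in 1° steps, the direction whose sorted center projections
cluster into the fewest, tightest groups (largest normalized maximum gap)
is taken as across-row, clusters are split at half the maximum gap, and the
scale is `known_row_spacing_cm / median adjacent-cluster distance`.  An
exhaustive angle scan replaced a principal-axis estimate because the
along-row and across-row variances of a field are often too close for PCA
to orient reliably.  The estimator refuses inputs with fewer than 10
centers, no periodic structure (clustering score < 0.08), or
mostly-singleton clusters (collinear points).

## Mask construction

A plant annotation is a set of center points; bounding-box annotations are
reduced to their midpoints first.  Rasterization paints the set of pixels
whose centers lie within 4 cm of each point (pixel-center-in-circle
membership — an unambiguous, testable rule); overlapping discs merge and
out-of-bounds parts clip.  Foreground is 255, background 0, and 8-connected
foreground is the connectivity convention everywhere.

## Synthetic scenes

The generator emulates early-season row-crop orthomosaic fragments:

- **Rows**: parallel lines at `row_spacing_cm` (bundled regimes: 45 and
  90 cm) at a configurable angle, with a small Gaussian wobble
  (σ = 3 % of spacing) per plant.  Each row has an independent sowing
  phase so in-row slots do not align across rows — aligned slots create
  artificial full-height background corridors that distort run-length
  statistics and do not occur in drilled fields.
- **In-row placement**: slots every `in_row_spacing_cm` with ±15 % uniform
  jitter; each plant missing with probability `missing_rate`.
- **Touching pairs**: with probability `touch_rate` per in-row neighbour
  pair, the second plant is pulled to a distance drawn uniformly in
  (0.8 r, 1.6 r) of the first, so their 4-cm mask discs merge into one
  elongated contour.  Plant count is conserved — touching is a spacing
  collapse, not extra plants — which is exactly the merged-contour error
  regime that depresses component counts and inflates GLRM long-run
  emphasis.
- **Appearance**: plants are radial green blobs (radius `plant_radius_cm`,
  default 5 cm ± 20 %, soft edge, per-plant brightness noise) over a brown
  soil field built from a low-frequency luminance surface plus per-pixel
  speckle.  Weeds are smaller green-ish blobs at Poisson-random off-row
  positions, absent from the ground truth.  Photorealism is deliberately
  out of scope: the appearance model is just rich enough that segmentation
  is a non-trivial but CPU-learnable problem.
- **Annotation degradation** emulates uncorrected public markup: Gaussian
  center jitter, random drops, Poisson spurious centers, and box-mode
  (centers re-derived from integer-cm bounding boxes, adding quantization).
  No quantitative description of real uncorrected-markup error exists, so
  these knobs are free parameters; the bundled degraded regime uses 2 cm
  jitter, 10 % drops, 1 spurious center per 100 m², box mode.

What passing tests on these scenes do **not** show: robustness to
perspective and stitching artifacts, radiometric variation across dates,
real weed morphology, or canopy shapes beyond discs.  Results on synthetic
scenes bound the pipeline's correctness, not its field accuracy.

## Segmentation model

A U-Net: residual encoder (basic-block [2,2,2,2] and [3,4,6,3] profiles,
bottleneck [3,4,6,3] profile) downsampling 32×, decoder with nearest ×2
upsampling, skip concatenation from every encoder resolution, and two
conv-BN-ReLU stages per decoder block; a 3×3 conv head outputs one logit
per pixel.  At width multiplier 1.0 and 512-px tiles the 18-layer encoder
bottleneck is 512 channels at 16×16.  `width_multiplier` and
`input_tile_px` are desk-scale knobs; the bundled pilot uses the 18-layer
profile at width 0.25 with 128-px tiles (≈ 0.9 M parameters).

The layers (convolution via im2col + BLAS matmul, batch normalization,
ReLU, 3×3/stride-2 max pooling, nearest upsampling), backpropagation and
the Adam optimizer are implemented in numpy inside the package; training is
single-CPU and deterministic for a fixed seed.  Encoders start from
He-normal random weights — no pretrained initialization.

**Loss.** DiceCE = binary cross-entropy + (1 − Dice similarity), with
Dice = (2 Σ p·t + ε)/(Σ p + Σ t + ε) and smoothing ε = 1 (standard
stabilization).  The output head is a sigmoid; predictions threshold at
0.5.  Closed forms used as tests: perfect hard predictions give ≈ 0; a
uniform-0.5 map against an empty target gives ln 2 + 1 − 1/(N/2 + 1).

**Training.** Adam, batch 8, learning rate linear from `lr_start` to
`lr_end` over epochs (reference regime: 1e-4 → 1e-6 over 100 epochs; the
pilot uses 2e-3 → 2e-5 over 10 epochs, scaled for the much smaller model
and dataset).  The best epoch is selected by validation IoU (pooled
intersection/union over the split).  Divergence (non-finite loss) aborts
with the epoch index.

**Augmentation** (optional, geometric ops applied identically to image and
mask, mask resampled nearest): rotation 0–90°, scale jitter ±30 %,
horizontal/vertical flips, brightness/contrast and gamma on the image only,
then a random crop.

**Tiled inference.** Whole images are processed as overlapping tiles
(default overlap 64 px at full scale, 32 at pilot scale); overlapping
probabilities are mean-blended before thresholding, suppressing seam
artifacts.  Images smaller than a tile are reflect-padded and cropped back.

## Counting

Plants = maximal 8-connected foreground components with area ≥
`min_area_px`.  The default threshold 10 px is ≈ 20 % of a radius-4 disc
(area ≈ 50 px): large enough to remove speckle, small enough to keep a
half-clipped boundary plant.  Centroids are unweighted means of member
pixel centers; contours are marching-squares outer boundaries.  Density is
`count / area_m2 × 10⁴` plants per hectare.

## Evaluation

Pixel IoU is |A∩B|/|A∪B| over whole masks (the alternative — averaging
over matched contour pairs — was considered and rejected as ambiguous for
merged regions); two empty masks score 1 by identity semantics.  Count
metrics are computed over non-overlapping tiles (reference size 20 m ×
20 m = 2000 px; desk-scale scenes use 256 px): MAE, MAPE, Pearson on raw
counts, Spearman with average-rank ties.  MAPE divides by the **predicted**
series — faithful to the method being implemented even though the
conventional denominator is the reference — with a switch for the
conventional form; tiles empty in both markups are excluded from MAPE
(logged) and any other zero predicted count makes MAPE undefined with a
warning.  A region straddling a tile boundary is counted in every tile it
touches, so tile sums can exceed the whole-scene count by the number of
straddlers; this is documented behavior, not a bug.

## Texture features

Computed on binary masks at native gray levels {0, 255} (no
re-quantization — on sparse masks the GLCM mean then lives on the 0–255
scale, i.e. 255 × foreground pair fraction).  Eight displacement vectors
(±1,0), (0,±1), (±1,±1); features are arithmetic means over the eight.
Opposite displacements are both in the set, so the averaged GLCM features
are symmetric without per-matrix symmetrization.

- GLCM: P[i,j] = normalized count of pixel pairs (p, p+d) inside the tile.
  Mean = Σ level·marginal; correlation = standardized covariance, reported
  as undefined (NaN, never 0) when a marginal is constant.
- GLRM (Galloway definitions): R[l, k] counts maximal runs of level l and
  length k along scan lines of the direction.  Long-run emphasis =
  Σ R·k²/n_runs; run percentage = n_runs/n_pixels (1 exactly when no two
  adjacent pixels share a value).

Per-tile profiles use non-overlapping tiles (reference 1000 px; desk scale
256 px); constant tiles are flagged and their undefined correlation dropped
pairwise from comparisons.  The markup comparison reports, per feature,
means, mean difference (predicted − manual), a paired two-sided t-test
(Wilcoxon signed-rank available as an option; the significance test used in
the reference analysis is unnamed), the OLS fit of predicted on manual
(manual on the X axis), and Pearson r.

Mechanistic properties the synthetic scenes reproduce: halving row spacing
at fixed plant size raises GLCM mean (denser planting); touching-pair
merging inflates GLRM long-run emphasis relative to a non-touching mask of
the same plant count.

## Experiments and the pilot benchmark

`ExperimentConfig` mirrors the study pattern with bundled dataset tags:
`hq-a`/`hq-b`/`hq-c` are disjoint clean scene sets (train/validation/test —
the tags, not an in-set split, are the leakage boundary) and `lq` is the
degraded-markup stratum; each tag draws scenes from its own seed stream.
The pilot benchmark trains the 18-layer/width-0.25 model on 12 clean
512-px scenes (192 tiles of 128 px) for 10 epochs and scores 6 held-out
scenes: validation IoU, pooled per-tile count agreement (the desk-scale
analogue of a per-experiment accuracy table), and the pooled
truth-vs-predicted texture comparison.  Problem sizes were chosen so the
full pipeline runs in minutes on one CPU while leaving clear margins over
the quality thresholds the tests assert (validation IoU ≥ 0.3, held-out
count r ≥ 0.9, MAPE ≤ 15 %).

## Numerical notes and limitations

- float32 weights/activations; float64 for losses and metrics.
- Determinism: all randomness flows from `numpy.random.Generator` seeds;
  identical (config, seed) reruns give identical histories on one machine.
  Bit-identical results across BLAS builds are not guaranteed.
- Batch normalization uses batch statistics in training and running
  averages (momentum 0.1) in inference; very small batches make the two
  diverge early in training.
- The counting stage performs no watershed or row-model splitting of merged
  plants; merged pairs undercount by design, which is precisely the error
  mode the texture comparison quantifies.
- `infer_scale_from_rows` assumes a single dominant row direction and
  near-constant spacing; curved rows or mixed plantings defeat it.
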