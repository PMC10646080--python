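# Methods

## Segmentation model

The segmenter is an encoder–decoder U-Net whose convolutional blocks learn
features at two spatial scales simultaneously. Each multi-scale block runs a
3×3 and a 7×7 convolution branch in parallel (half the output channels each),
concatenates them, applies batch normalization and ReLU, fuses with a 1×1
convolution plus a second batch normalization, and adds a residual shortcut
(1×1-projected when the channel count changes) before the output ReLU. The
rationale is the size heterogeneity of organoids in a single frame: a tight
kernel resolves small buds, a wide one covers large cysts, and the residual
path keeps optimization stable at the depths used. Downsampling is 2× max
pooling; upsampling is 2× nearest-neighbor followed by a 1×1 channel-halving
convolution and concatenation with the encoder skip; the head is a 1×1
convolution with a sigmoid producing one foreground-probability map the same
size as the input.

Default widths are `depth=4`, `base_channels=32` with channel doubling per
level; the test suite and acceptance run use a reduced `depth=3`,
`base_channels=8` model, which is sufficient for the synthetic scenes and
trains on one CPU in minutes. Weight initialization is He-normal, seeded, so
two builds with the same seed are bit-identical.

The whole stack — convolution (evaluated as k² shifted BLAS contractions),
batch norm, pooling, the block graph, and SGD with momentum — is NumPy with
hand-written backward passes, verified layer-by-layer against central finite
differences in float64 (the model exposes a `cast` method for exactly this).
Whole-image inference reflect-pads to a multiple of 2^depth, runs one forward
pass, crops back, and binarizes at a strict `probability > 0.5` (exposed as a
flag); no tiling is needed at these frame sizes.

## Training objective and loop

The loss is an unweighted compound of two terms on the sigmoid probabilities:
soft dice loss `1 − (2Σpg + ε)/(Σp + Σg + ε)` with smoothing `ε = 1`
(computed per sample and averaged over the batch) and mean per-pixel binary
cross-entropy with probabilities clipped to `(δ, 1−δ)`, `δ = 1e−7`. The
smoothing and clip constants are numerical-safety choices; gradients are
analytic and tested against finite differences.

Each epoch draws one random crop per training image (512 px at full scale,
128 px in the reduced runs), applies a jointly sampled augmentation —
per-axis flips at p = 0.5, rotation uniform in ±180°, affine scale 0.9–1.1
and translation up to 10 %, plus an image-only Gaussian blur with σ ∈ [0,
1.5] — and steps SGD (learning rate 0.001, momentum 0.9, batch 8). The
transform family is standard for microscopy; the magnitudes are package
defaults, all exposed in `TrainConfig`. Masks are resampled
nearest-neighbor so they stay strictly binary. Validation runs whole-image
inference each epoch and records mean DSC; the returned weights are those of
the best-validation epoch. With a fixed seed the entire history is
reproducible on one device.

## Post-processing and object selection

`clean_mask` applies opening-then-closing with a 3×3 elliptical structuring
element (default 2 iterations), fills fully enclosed background holes, and
deletes components below `min_area_px` (default 50 px — a noise floor,
deliberately distinct from the biological size filter). The sequence is
repeated until the mask stops changing (a fixed point is reached within one
or two passes in practice), which makes the operation idempotent by
construction while preserving the stated postconditions: no enclosed holes,
no undersized components.

`label_contours` labels 8-connected components 1..N in raster order of each
component's topmost-then-leftmost pixel — an explicit convention, since
"ascending order" is otherwise ambiguous — and traces each boundary as a
closed sub-pixel polygon (marching squares at level 0.5).

`filter_objects` then drops objects touching any frame border and objects
with equivalent-circle diameter below 40 µm, the threshold below which a
structure is not counted as an actual organoid. "Size" is interpreted as
equivalent diameter √(4A/π); major axis or minimum Feret would be defensible
alternatives, and the threshold and border rule are both exposed.

## Morphometrics

Area is the pixel count; axes and eccentricity come from the
second-central-moment equivalent ellipse (scikit-image `regionprops`
convention); solidity is area over convex-hull area. Perimeter uses the
Crofton-formula estimator (4 directions): a raw marching-squares polygon or
unit/√2 step count systematically overestimates a smooth outline by 5–8 %,
which would bias circularity by >10 %, while the Crofton estimate is within
about 1 % on discs and ellipses at the sizes measured here. Circularity and
roundness can slightly exceed 1 on digitized discs; values are reported
unclamped. Unit conversion multiplies lengths by the µm/px ratio r and areas
by r²; dimensionless metrics are unchanged. Calibration is a supplied
configuration value, not read from the burned-in scale bar (scale-bar OCR is
out of scope and fragile).

Per-image summaries are totals of the size metrics and the unweighted mean
eccentricity over the retained (filtered) objects only; an empty image yields
zero totals and an explicitly undefined (None) mean.

## Evaluation

Pixel agreement is DSC, with both-empty defined as 1 (vacuous agreement).
Object detection uses greedy one-to-one matching by descending IoU at a 0.5
threshold: matched organoids are TP, unmatched organoids FN, predictions
matching nothing (or matching a distractor) FP, and unmatched distractors TN.
The negative class is the annotated out-of-focus distractor set — a synthetic
convenience, since real detection studies rarely define negatives explicitly;
both the matching rule and threshold are exposed, and rates with zero
denominators are flagged undefined rather than propagated as NaN.

Pearson r (with its t-test P-value) and ordinary least squares (slope,
intercept, R², P) are delegated to scipy behind the module surface, with a
defined R² = 0 for a flat response. Lin's concordance correlation coefficient
`ρ_c = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²)` is implemented here with biased (1/n)
moment estimators, and its 95 % CI applies the Fisher z-transform with Lin's
asymptotic standard error. The invariant |CCC| ≤ |r| is property-tested.

## Growth analytics

Each replicate well is normalized to its own Day-1 value (so Day 1 maps to
exactly 1), then mean ± SD are taken across replicates. Correlation of each
per-image parameter (total area, total perimeter, count, mean eccentricity)
against the viability readout ranks parameters by r. The subculture time
point is the first day whose relative day-over-day growth falls below 10 % —
a deliberate operationalization of "growth has slowed", with the fraction
exposed as a parameter.

## Synthetic data

The generator emulates the imaging regime the pipeline targets: 8-bit frames
with a mild illumination tilt and Gaussian noise (σ = 8); organoids as
rotated ellipses with a bright lumen (+60 over background) and a 2.5 px dark
rim (−45), sizes drawn from a lognormal equivalent-diameter distribution
(median 80 µm, log-σ 0.4, truncated to 30–250 µm at 2 µm/px) with
eccentricities in [0, 0.8]; and out-of-focus distractors as low-contrast
blobs blurred with σ equal to half their radius, excluded from ground truth.
In-focus organoids are placed without overlap; border-cropped objects appear
only when enabled. Growth series scale semi-axes by √(daily factor), hold
layouts fixed (reserving frame room for the final day, so late-day organoids
may touch, as real cultures do), optionally taper growth after a plateau day,
and pair each well-day with a viability value `k · total analytic area ·
(1 + ε)`, `ε ~ N(0, noise²)`. Well plates sweep a two-fold serial dilution of
organoid counts.

What the generator does **not** model: optics (defocus is a blur
approximation, not a point-spread function), Matrigel texture, budding/crypt
morphologies, overlapping or touching in-focus organoids on a single day, and
intensity heterogeneity inside the lumen. Passing tests therefore demonstrate
that the pipeline's machinery is correct and learnable on this regime — not
that the trained weights transfer to real microscope data, which is exactly
why the network is retrainable from user-supplied image/mask pairs.

## Problem sizes and numerical choices

The test suite and acceptance script run a scaled-down version of the full
study design: 256×256 scenes in a 15/5/10 train/validation/test split,
reduced-width model (depth 3, 8 base channels), 128 px crops, 30 epochs —
chosen so the whole pipeline exercises end to end in a few CPU-minutes while
leaving wide margins over the quantitative thresholds (the reduced run
reaches post-processed DSC ≈ 0.95 on synthetic test scenes). The 90-well
viability study uses 224×224 wells cycling 8/6/4/2/1 organoids with 5 %
viability noise; growth series use 3 wells × 5 days with area doubling and a
day-4 plateau. Float32 is used for training (float64 for gradient
verification); all stochastic steps flow from explicit integer seeds.

## Known limitations

Touching or overlapping organoids are segmented as one component — splitting
them (e.g. watershed on the probability map) is future work. The detection
negative class is generator-defined, so detection specificity is only
meaningful where annotated non-organoid instances exist. Perimeter, and hence
circularity, remains a biased estimate at very small sizes (< ~15 px radius).
Training is single-device, full-precision, and deliberately free of learning
rate schedules; at full frame scale (1600×1200, depth 4, width 32) the NumPy
implementation trains in hours, not minutes, and users wanting large-scale
retraining may prefer to port `ModelConfig` to a GPU framework — the
architecture is fully specified above.
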