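# Methods

This note documents the models, numerical conventions, and design choices
behind `gtvseg`, and what the synthetic phantom experiments do and do not
demonstrate about real MRI data.

## Problem setting

Delineation of the primary gross tumor volume (GTVp, label 1) and
metastatic lymph nodes (GTVn, label 2) against background (label 0) on
T2-weighted head-and-neck MRI. Inputs are 3D NIfTI volumes of arbitrary
voxel spacing; the pipeline resamples to a working grid, trains a 3D U-Net
on patches, and predicts whole volumes by sliding-window inference, finally
restoring predictions to the input's native grid. A second "prior-guided"
mode consumes four channels — a mid-treatment scan, a registered
pre-treatment scan, and the two binary pre-treatment tumor masks — with
z-scoring applied to the image channels only.

## Coordinate and IO conventions

Voxel indices are 0-based in `(x, y, z)` order matching the NIfTI header
spacing. Every image is reoriented to the closest canonical (RAS)
orientation on read; `origin_meta` stores the source affine and the
orientation transform so writes and `restore_to_origin` reproduce the
on-disk grid exactly. Intensities are float32 in memory; masks uint8.
Resampling output shape per axis is `round(shape·spacing/target)` with
ties away from zero (minimum 1), using linear interpolation for images and
nearest-neighbor for masks on a corner-aligned voxel-center grid
(`scipy.ndimage.map_coordinates`, edge-clamped). Nearest-neighbor
guarantees the label set never grows and no fractional labels appear.

## Normalization

`normalize_patch` z-scores with the population (divide-by-N) standard
deviation; a zero-variance patch (e.g. a fully padded corner) maps to
zeros rather than raising. Patch-wise normalization is affine-invariant:
`normalize(a·x + b) = normalize(x)` for any gain `a > 0` and offset `b`,
which is precisely why it removes scanner-dependent intensity scales and
the location dependence of patch statistics that image-wise normalization
leaves behind. The image-wise mode is retained as an explicit baseline so
the two can be compared; at inference, normalization is applied inside the
sliding-window loop (`normalize="patch"`), to each window after extraction.

## Patch sampling

Training patches (default 320×320×64 at full scale; 32×32×16 in the
desk-scale presets) are sampled so a `fg_fraction` (default 0.9) of
patches contain at least one tumor voxel: a tumor class is drawn uniformly
among the classes present in the mask, then a voxel of that class
uniformly, then the patch start uniformly among starts covering that
voxel. The class-balanced first step is a deliberate choice: drawing
target voxels uniformly over all tumor voxels lets the large primary
volume crowd out the much smaller nodes (in desk-scale runs the node class
then never trains in the available iterations); balancing classes
preserves the stated "90% of patches contain tumor" contract while giving
both classes comparable exposure. Volumes smaller than the patch are
zero-padded symmetrically before extraction; padding happens before
normalization.

## Augmentation

Six transforms, each fired independently with probability `p`:
axis flips; in-plane rotation uniform in ±15° (in-plane only, given the
strongly anisotropic voxels); gamma contrast with γ ∈ [0.8, 1.25] on the
min–max-normalized patch; a smooth multiplicative bias field (cubic
upsampling of a 4³ uniform grid, relative amplitude 0.3); motion ghosting
(a rolled copy along one random axis mixed in with weight up to 0.3); and
additive Gaussian noise with sd up to 0.1 of the patch sd. The parameter
ranges are conventional choices, each exposed in `AugmentConfig`. Spatial
transforms are applied identically to image (linear) and mask
(nearest-neighbor, zero fill), so the mask label set can only shrink. In
the four-channel prior-guided mode, spatial transforms move every channel
with shared parameters (binary prior channels via nearest-neighbor) and
intensity transforms touch only the two image channels, drawing one
parameter set for both — a desk-scale simplification of per-acquisition
corruption.

The firing probability follows a blockwise-linear schedule: with
`k = iteration // block` and `K = total // block`,
`p = p_start + (p_end − p_start)·k/(K−1)` — piecewise constant over
1K-batch blocks, attaining exactly 0.05 in the first block and 0.25 in the
last (defaults). Iterations in a ragged final partial block reuse the last
full block's probability. Augmentation precedes patch normalization, so
injected bias/noise statistics are re-standardized; the ordering is a
design choice.

## Network

A six-stage 3D U-Net built from conv→instance-norm→ReLU blocks (two per
stage on both paths), 2×2×2 max pooling, channel doubling per stage from
`base_width` 32, and a decoder that enters each resolution via a 1×1×1
conv block halving the channels followed by nearest-neighbor upsampling
and concatenation with the encoder skip. Per-stage kernel edges are
configurable; the default `[3,3,3,3,1,1]` uses pointwise convolutions in
the two widest stages, which moves the trainable-parameter total from
85,599,715 (~86M, all-3×3×3) to 14,034,403 (~14M). Instance norm carries
learnable affine parameters and convolutions carry biases; parameter
counts include both. A 1×1×1 head plus softmax yields per-voxel class
probabilities. `instance_norm=False` produces strictly voxelwise networks
(used as the sliding-window oracle in tests, since instance normalization
introduces patch-level statistics).

The layers, backpropagation, and Adam are implemented on numpy
(`gtvseg._nn`): convolutions accumulate one BLAS contraction per kernel
offset; gradients are verified against central finite differences in
float64 in the test suite. Everything is deterministic given the seeds.

## Loss

Per class `c` present in the batch ground truth (Σy_c > 0, background
included), the term `1 − 2Σ y_c p̂_c / (Σ y_c + Σ p̂_c + ε)` is pooled over
the entire batch; the loss is the mean over present classes, so absent
classes contribute neither loss nor gradient. ε = 1e-7 guards the
pathological Σp̂ = 0 denominator only; presence-masking already prevents
0/0 for the truth side. For hard (binary) predictions and a single class
the term equals `1 − DSCagg` exactly.

## Metrics

`dsc` implements the per-pair Dice coefficient; when both masks are empty
it returns 1 by default (a vacuously perfect prediction — configurable),
and 0 when exactly one is empty. `dsc_agg` pools intersections and sizes
over all pairs before dividing, with the same all-empty convention. The
cohort score is the mean of per-class DSCagg over {GTVp, GTVn}.
Argmax labeling breaks ties toward the lowest class index (background).

## Sliding-window inference

Windows start at 0 with step `stride` per axis; the final start is clamped
to `volume − patch` so the last window ends flush with the volume edge,
guaranteeing full coverage without padding whenever the volume is at least
patch-sized (smaller volumes are padded out and cropped back). Per-voxel
output is `Σ wᵢ p̂ᵢ / Σ wᵢ` over covering windows, accumulated in float32
on two buffers and divided once; since each window's output is a
probability simplex, the weighted mean is too.

The Gaussian weight map is a separable product of per-axis profiles.
Distances are measured from the continuous axis center `(L−1)/2`; the
profile is calibrated so the *central voxel(s)* (distance 0, or 1/2 on
even-length axes) carry weight exactly 1 and the *boundary voxels* carry
exactly `edge_value` (default 0.1): σ² = (d_b² − d_c²)/(2·ln(1/edge)),
with the profile evaluated as exp(−(d² − d_c²)/(2σ²)). Face-center
boundary voxels therefore weigh exactly 0.1 and corners exactly 0.001.
"Edges" is interpreted per axis; axes of length ≤ 2 degenerate to uniform
weights. Uniform weighting (plain averaging) is the baseline alternative;
the two agree exactly when stride = patch (no overlap), and the weight
choice can never affect voxels covered by a single window.

Ensembling averages the softmax volumes of the member models before the
argmax; predictions are then restored to the original grid with
nearest-neighbor interpolation.

## Training loop

Two modes share one loop. Task 1 trains on single-channel scans. Task 2
(prior-guided) trains a four-input-channel network on registered
pre-/mid-treatment pairs: channels are the mid scan, the pre scan, and the
two binary pre-treatment tumor masks; only the image channels are
z-scored, and the mid-treatment mask is the target.

Adam (β = 0.9/0.999, ε = 1e-8 — conventional defaults) under a cosine
learning-rate decay `lr_end + (lr_start − lr_end)(1 + cos(πt/T))/2`,
defaults 1e-3 → 1e-5. Batch size 2. Every `eval_every` iterations the
model is validated by sliding-window inference over the held-out fold and
the checkpoint with the best validation mean DSCagg (never training loss)
is retained. Folds are patient-wise: each patient's images land in exactly
one of k near-equally sized folds, deterministically per seed. No
post-processing is applied after the argmax.

## Synthetic phantoms

The generator emulates the *properties the method targets*, not anatomy:

* smooth band-limited background "tissue" (cubic upsampling of a 6³
  Gaussian grid, relative amplitude 0.15, floor-clipped);
* lesions as sharp-edged ellipsoids brighter than background — GTVp one
  large central mass (semi-axes 10–15% of the x/y extent), GTVn small
  peripheral nodes (5–9%) — with intensity contrast defaulting to +30%
  (GTVp) and +50% (GTVn) of the background mean. Size and position, not
  just intensity, separate the classes: after patch-wise z-scoring,
  absolute intensity is scale-ambiguous, so geometry must carry class
  identity just as it does for a radiologist;
* a smooth multiplicative bias field (amplitude 0.2), then a global
  per-image intensity gain/offset emulating the non-standardized MRI
  scale, then additive Gaussian noise (sd 5% of the background mean,
  scaled with the gain). The corruption is exactly affine in the gain, so
  patch-normalized patches from differently scaled copies of the same
  anatomy agree to float precision — the property the normalization tests
  assert.

Paired pre-/mid-treatment phantoms share anatomy and lesion geometry, with
mid lesion semi-axes multiplied by a shrink factor (volume ∝ shrink³) and
independent intensity corruptions — registered by construction.

Cohorts draw per-image gains log-uniformly from [0.5, 5] and offsets from
[−0.5, 0.5], so whole-image statistics vary severalfold across patients
while normalized patches are identically standardized.

**What phantom results do not show:** real anatomical context (air,
muscle, vessels, nodal chains), real lesion texture and infiltrative
margins, scanner artifacts beyond the simulated bias/ghosting, or
realistic inter-observer label noise. Passing the end-to-end phantom test
demonstrates that the pipeline's mechanics (sampling, normalization,
augmentation, optimization, inference, metric bookkeeping) are correct and
that the network can learn size/contrast-defined targets from few
examples — not that the desk-scale network would segment clinical MRI.

## Desk-scale experiment sizes

Tests train a base-width-4, 3-stage U-Net on 32×32×16 patches from six
96×96×48 phantoms (spacing 1×1×2 mm), 2000 iterations with validation
every 250 — about six minutes on one CPU. The end-to-end bar (validation
mean DSCagg > 0.5) was established with high-contrast lesions
(+100%/+140%), where the run reaches 0.573: nodes are segmented at DSCagg
≈ 0.9 while the primary volume retains background false positives at this
scale — the same class asymmetry reported on real data. The full-scale
protocol (patch 320×320×64, stride 80×80×16, 100K iterations, batch 2,
working spacing 0.5×0.5×2 mm) is expressed by the same configuration
objects but is far outside CPU budgets.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; it is meant for
  correctness and desk-scale experiments, not GPU-scale training.
* Mixed-precision training is not implemented (full precision only;
  float64 is available for numerical verification).
* `restore_to_origin` assumes the working grid was derived from the
  recorded source grid by resampling; arbitrary affine mismatches
  (rotation between grids) are out of scope, as is registration generally.
* The empty-vs-empty Dice convention (return 1) is a reporting choice;
  pooled DSCagg is insensitive to it unless an entire evaluation set is
  empty.
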