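# Methods

## Problem and data model

The package segments nuclei in H&E-stained histopathology tiles:
every pixel is classified as nucleus/tumor (1) or background (0).
In-memory conventions are fixed across modules: images are
`(H, W, 3)` float arrays in `[0, 1]`, masks are `(H, W)` arrays in
`{0, 1}`, coordinates are row-major with the origin at the top-left.
On disk, masks are 8-bit PNGs encoded 0/255, and a dataset directory
pairs `<id>.png|tif` with `<id>_mask.png`.

## Synthetic data generator

Real H&E tiles at this scale show dark bluish-purple, roughly
elliptical, often overlapping nuclei on a pale pink background. The
generator renders exactly that reduced model: `n_nuclei` filled
ellipses with uniformly random center, orientation, radius
(`radius_range`, in pixels) and eccentricity, colored
`nucleus_color = (0.35, 0.25, 0.55)` on `background_color =
(0.90, 0.75, 0.80)` (hematoxylin/eosin proxies chosen to preserve the
luminance ordering the dark-is-nucleus heuristic relies on), plus
per-channel additive Gaussian noise (`noise_sd`, clipped to `[0, 1]`).
The mask is the union of the rendered ellipses and is never touched by
noise, so ground truth is pixel-exact. With `allow_overlap=False`,
nuclei are placed by rejection sampling against already-occupied
pixels (500 attempts, then an error). Defaults describe a 512×512 tile
with 40 nuclei of radius 8–24 px and noise sd 0.03 — a plausible
density for breast-tissue crops; tests and benchmarks use smaller
canvases.

What the generator does **not** emulate: stain variability and uneven
illumination, textured chromatin and nucleoli, out-of-focus blur,
touching-nucleus intensity gradients, and non-nuclear hematoxylin
uptake. Passing the synthetic benchmarks therefore demonstrates that
the pipelines are implemented correctly and can recover structure
under the stated contrast/noise conditions — not that they reach any
particular accuracy on real histology.

## Patching

Both branches consume fixed-size square patches cut on a regular grid
(default 32×32, non-overlapping). Sizes that the grid does not cover
exactly are reflect-padded on the bottom/right to the smallest covering
size (reflection avoids border artifacts; the choice only matters for
sizes not divisible by the stride). Reassembly broadcasts each patch
label (or places each mask patch), takes a per-pixel majority over
covering patches when strides overlap — ties go to foreground, to
favor recall on nuclei — and crops the padding, so
`assemble(extract(x)) == x` exactly. Ground-truth patch labels use a
configurable `positive_fraction` threshold on the patch's foreground
fraction (default 0.5, i.e. majority — a symmetric default since no
canonical rule exists). Rotation augmentation rotates image and mask
identically; right angles are lossless, arbitrary angles resample
bilinearly (image) / nearest-neighbor (mask, to stay binary) on a
fixed-size canvas with reflect fill.

## NumPy layer engine

The networks run on a purpose-built NumPy engine
(`histoseg.nn`) with explicit backpropagation, scoped to exactly what
the architectures need: stride-1 'same' convolutions (im2col + GEMM),
batch normalization (batch statistics in training, running averages at
inference, momentum 0.1, eps 1e-5), ReLU/sigmoid, 2×2 max pooling
(ties to the first window element), 2×2-stride-2 transposed
convolutions, dense layers, mean-squared-error and softmax
cross-entropy losses, and Adam (β₁ 0.9, β₂ 0.999, eps 1e-8).
Weights are He-normal initialized from a seeded generator; all tensors
are float32 NCHW. Gradients of every layer are verified against
central finite differences in the test suite. Being pure NumPy, the
engine is single-threaded-deterministic: fixed seeds reproduce
training histories and predicted masks bit-identically on the same
platform/BLAS.

## Unsupervised branch (CAE + K-means)

The autoencoder's encoder is `N` levels of [conv3×3 (filters doubling
from `C`) → batch-norm → ReLU → max-pool 2×2] followed by a dense
bottleneck of exactly `Z` units; the decoder mirrors it with 2×2
up-convolutions and ends in a sigmoid so reconstructions stay in
`[0, 1]`. "Normalization" is realized as batch normalization (the
standard choice for convolutional encoders of this vintage;
configurable off). The reconstruction loss is per-pixel MSE; the
optimizer is Adam at lr 1e-3, batch 32 (both configurable). Defaults
`N=3, C=16, Z=64` on 32×32 patches put the bottleneck (64) far below
the input dimensionality (3072) while keeping `32 / 2³ = 4` integral.

Clustering is sequential, not joint: the CAE is trained to
convergence first, then codes are clustered (no DEC-style fine-tuning).
`fit_kmeans2` runs Lloyd iterations from k-means++ starts, best of
`n_restarts=10` by inertia; on small inputs (≤ 64 distinct codes) it
additionally runs Lloyd from every distinct pair of points — with
K = 2 the optimal partition is itself a Lloyd fixed point, so dense
deterministic seeding makes the small-sample optimum reliably
attainable where a handful of random restarts can stall in a local
minimum. All-identical codes raise a degenerate-input error rather
than returning an empty cluster. Nearest-centroid ties resolve to the
lower centroid index.

Cluster → class correspondence is underdetermined by clustering, so it
is resolved explicitly: with reference masks, the bijection maximizing
pixel accuracy is chosen (ties keep cluster 0 as background);
without, the cluster whose member patches have lower mean luminance
(Rec. 601 weights) is called tumor, since hematoxylin-stained nuclei
are darker than eosin background. Segmentation inherits each patch's
class for all its pixels — patch-level granularity is intrinsic to
this branch; running the encoder over an overlapping grid (stride <
patch size) with per-pixel voting refines the effective resolution to
the stride.

## Supervised branch (improved U-Net, FCN baseline)

Encoder blocks are `convs_per_block` repetitions of [conv3×3 →
batch-norm → ReLU] followed by 2×2 max-pool, with feature width
doubling per level; the symmetric decoder uses 2×2 up-convolutions and
concatenates the matching encoder feature map at every level. The head
is a 1×1 convolution to `n_classes` followed by the per-pixel channel
softmax, trained with pixel-wise cross-entropy (Adam, lr 1e-3). The
classic architecture has `convs_per_block=2`; the improved variant
deepens every block (default 3). Exposing the depth of the blocks as a
knob covers the reasonable readings of "adding layers to encoder and
decoder" and makes the classic/improved difference testable by
parameter count.

The FCN baseline is an AlexNet-style convolutional encoder —
large-kernel first convolution (7×7, then 5×5, then 3×3), max-pool
halving per level, no skip connections — followed by a 1×1
classifier stage and stacked 2×2 transposed convolutions back to input
resolution. It is trained from scratch by the same `train_segmenter`
(pre-trained weights are deliberately not used). Its coarse,
skip-free decoder is what makes it a meaningful lower baseline:
boundary detail lost in the encoder cannot be reinjected.

Prediction tiles an arbitrary-size image on the training patch grid
(reflect-padded), averages class probabilities over covering tiles,
and takes the per-pixel argmax with the exact-0.5 tie resolved to
foreground (documented recall-favoring rule).

## Benchmarks and problem sizes

`histoseg.benchmarks` fixes three desk-scale conditions used by the
acceptance tests and `scripts/acceptance.py` (sizes chosen to make a
full from-scratch run a few CPU-minutes while keeping every pipeline
stage non-trivial):

* **CAE learning** — default CAE on 200 high-contrast 32×32 patches,
  20 epochs; measures final/initial reconstruction MSE.
* **Unsupervised recovery** — 20 images, 128×128, 8 nuclei of radius
  14–22 px, noise sd 0.02; CAE `N=2, C=16, Z=32` on 16×16 patches
  (15 epochs), clustering on all patch codes, reference-mode mapping,
  segmentation at stride 4. The 16-px patch / 4-px stride choice sets
  the spatial granularity of this branch; 32-px patches are too coarse
  for nuclei of this size, which is a property of patch-level
  clustering, not of the training.
* **Supervised benchmark** — improved U-Net (depth 3, base 8 filters,
  3 convs/block) and FCN trained 30 epochs on 64 images of 64×64 and
  scored on 16 held-out images.

A single master seed drives data generation, initialization, shuffling
and clustering through deterministic sub-seeds; reruns are
bit-identical.

## Numerical choices and degenerate inputs

* Softmax is always computed with the per-pixel max subtracted
  (shift-invariant by the formula); probability maps sum to 1 per
  pixel within 1e-6 in float32.
* Metrics with zero denominators are reported as undefined (`None`)
  and excluded from aggregate means — never coerced to 0 or 1.
  Evaluating zero pixels is an error.
* Evaluation is computed on original (unpadded) image extents only.
* Mask thresholding on read uses strict `> 0.5` on the `[0, 1]` scale,
  so 128/255 rounds to foreground.
* Empty datasets, non-binary masks, shape mismatches, unmapped cluster
  models and untrained segmenters raise typed errors
  (`histoseg.errors`) rather than degrading silently.

## Known limitations

* The engine is CPU-only and unoptimized beyond BLAS-backed GEMMs;
  200-epoch full-scale training runs are out of intended scope.
* Batch normalization uses batch statistics during training, so
  per-epoch losses depend on batch composition (seeded shuffling makes
  this reproducible).
* The unsupervised branch's resolution is bounded by the patch stride;
  it cannot separate touching nuclei within one patch.
* The dark-is-nucleus mapping heuristic assumes H&E-like luminance
  ordering and will mislabel inverted-contrast stains; use
  reference-mode mapping there.
* Synthetic benchmarks bound correctness, not real-data performance
  (see the generator section).
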