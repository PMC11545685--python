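# Methods

`iousseg` implements real-time binary segmentation of liver vessels in
intraoperative ultrasound (IOUS) video frames with a *2D-weighted,
attention-enriched U-Net*: a compact encoder–decoder whose skip connections
are gated by a precomputed per-pixel saliency prior (the *weight map*).
This note records the model, the choices made where the design was open,
the synthetic data used to exercise it, and the problem sizes the shipped
tests and scripts run at.

## The segmentation model

**Inputs.** A grayscale frame and its weight map, both resized to a square
grid (canonically 256×256) and scaled to [0, 1]. The weight map is a prior
probability that a pixel belongs to a vessel; the model has no map-free
mode — the prior is consumed at training and inference alike.

**Encoder.** Five convolutional stages with deliberately few filters
(32, 32, 64, 64, 128), 3×3 kernels, ReLU activations, 2×2 max pooling
between stages. The small widths keep single-frame CPU/GPU inference fast
enough for intraoperative use.

**Weighted blocks.** At each encoder level *l* = 1..4 the learned feature
map `LFM_l` (side `S/2^(l−1)`, `z_l ∈ {32,32,64,64}` channels) is fused
with the pyramid level `w_l` of the weight map (side `S/2^l`, built by
repeated 2×2 max pooling — max rather than mean so that a small salient
structure survives into every level):

1. project `LFM_l` to 128 channels with a 1×1 convolution and 2×2-max-pool
   it to `Q_l`;
2. lift `w_l` to 128 channels with a 1×1 convolution + ReLU;
3. add the two element-wise; refine with a 3×3 (128-filter) convolution,
   ReLU, then a 1×1 convolution to a single channel;
4. a sigmoid turns that into the attention gate `X ∈ [0,1]` per pixel;
5. the gated skip is the element-wise product `O_l = X * Q_l`
   (128 channels, side `S/2^l`).

Two points here are genuine design choices rather than forced by the
architecture sketch: the feature pathway must be brought to the same
128-channel width as the lifted map before the addition (a 1×1 projection
is the minimal such lift, and matches the attention-gate literature the
design descends from), and `Q_l` is defined as the max-pooled *projected*
features so that gate and gated features share one grid.

**Decoder.** Four up-sampling stages (nearest-neighbour ×2 + 3×3
convolution + ReLU), each concatenating its gated skip `O_l`; a final
3×3 stage and a 1×1 head with sigmoid produce the per-pixel vessel
probability map at the input resolution. Sigmoids inside hidden decoder
layers would throttle gradients, so the sigmoid is head-only. Dropout is
present in the architecture but fixed at rate 0 by default.

**Initialisation.** He-uniform, seeded; biases zero. Nearest-neighbour
up-sampling avoids the checkerboard artifacts of transposed convolutions.

**Backend.** The network, its backpropagation and the Adam optimiser are a
compact NumPy implementation: convolutions are evaluated as one BLAS GEMM
over im2col patch matrices (nine slice copies of the padded input), the
input gradient by col2im scatter-add, and the weight gradient from the
cached forward patch matrix. Everything is float32 NHWC. On one CPU core
this sustains tens of GFLOP/s, enough to train the 1.12 M-parameter
network at reduced frame sides in minutes.

## Training recipe

Adam with learning rate 1e-3, batch size 16, no data augmentation,
100 epochs at full scale; one binary model per vessel label; frames are
treated as independent samples and shuffled across clips each epoch
(seeded). Patients are partitioned 60/10/30 into train/validation/test
*before* any frame is seen, by largest-remainder rounding (22 patients →
13/2/7) with at least one patient per partition; a clip inherits its
patient's partition, so no patient leaks across sets. Model selection
keeps the best-validation-Dice parameters.

The loss defaults to pixel-wise binary cross-entropy plus soft Dice loss
(`1 − (2Σpm+ε)/(Σp+Σm+ε)`, ε = 1e-6 for empty-mask stability) — the
standard pairing for heavily class-imbalanced binary segmentation; either
term can be selected alone.

## Saliency weight maps

The prior is estimated on SLIC superpixels (default K = 200,
compactness 10) by a bound-constrained quadratic program over per-superpixel
saliencies `s ∈ [0,1]^K`:

    min_s ‖s − f‖² + λ_c ⟨d, s²⟩ + λ_z ⟨f, (1−s)²⟩ + λ_s sᵀL s

with `f` the foreground likelihood (inverted mean intensity by default —
vessel lumina are anechoic; polarity configurable), `d` the normalised
distance to the centroid of the foreground mass, and `L` the Laplacian of
the superpixel adjacency graph with intensity-affinity edge weights
(σ = 0.15). The terms are, in order: a data term, a discount for
superpixels far from the foreground centre, a cost for assigning zero
saliency to foreground-like regions, and a smoothness/connectedness
surrogate. Defaults λ_c = 0.5, λ_z = 1, λ_s = 2 were chosen once on visual
inspection of phantom maps. The QP is solved by projected gradient with a
Lipschitz step bound, tolerance 1e-6, ≤ 500 iterations; the solution is
rasterised and min–max rescaled to [0, 1]. Because the likelihood is
computed on min–max-normalised intensities, the map is invariant to
positive rescaling of the frame. A constant frame carries no signal and
yields a uniform 0.5 map with a warning. Precomputed maps from any
external saliency system are a first-class bypass (8-bit PNG / float
TIFF loader with clipping).

## Preprocessing

*Quality filter.* Three degenerate-frame classes, checked in order:
**blackness** — ≥ 95% of pixels below 8-bit intensity 10 (robust to a few
bright artifacts); **no target** — an annotation mask is supplied and
empty; **blurry** — variance of a 3×3 Laplacian response on the [0,1]
grayscale below 1e-4. That threshold was calibrated once on phantom
statistics: sharp speckle frames score ≥ 3.7e-2, σ = 8 Gaussian-blurred
frames ≤ 6.2e-7, so the default sits mid-gap on a log scale and both
populations are orders of magnitude away from it.

*Normalisation.* Bilinear resize to the model grid and division by 255;
masks are resized nearest-neighbour so they stay strictly binary. The
operation is idempotent on already-normalised input.

*Clip splitting.* Recordings are cut wherever the mean absolute
inter-frame intensity difference (8-bit units) exceeds a configurable
threshold (default 25) — a reproducible automated proxy for the structural
changes a radiologist would mark; manual cut lists can be supplied instead
by splitting upstream.

The pipeline applies the quality filter at load time, before model-grid
normalisation; the filter-vs-split order is configurable by composing the
functions, since the statistics involved are per-frame.

## Evaluation

Pixel confusion counts (TP/TN/FP/FN) give recall, precision, accuracy,
IoU = TP/(TP+FN+FP) and Dice = 2TP/(2TP+FP+FN); the identity
Dice = 2·IoU/(1+IoU) holds exactly and is asserted in tests. AUC-ROC is
computed rank-based (Mann–Whitney, midrank ties) over the raw probability
map, making it invariant under strictly monotone transforms. Zero
denominators: both masks empty → vacuous agreement (1); a one-sided
undefined ratio (e.g. recall with empty truth) is reported as NaN and
skipped in aggregation. Aggregation is an unweighted per-frame mean ±
sample SD (ddof 1; a single frame reports SD 0) per vessel, columns in
the order Dice, IoU, Recall, Precision, Accuracy, AUC-ROC.

## Synthetic phantoms

The generator emulates the image statistics that matter for this task, not
ultrasound physics: elliptical anechoic vessel cross-sections (lumen 0.08)
on bright parenchyma (0.55) under multiplicative gamma speckle (shape 4–6,
mean 1, lightly blurred for spatial correlation), optional wedge-shaped
acoustic shadows (attenuation 0.4), per-clip linear probe drift, and three
injected degenerate-frame classes (near-black, vessel-free, σ = 8
blurred) with per-frame labels. Vessel radii default to 0.08–0.16 of the
frame side, matching the scale of hepatic vessel cross-sections in a
typical 6–8 cm field of view (a ~2 cm IVC lumen subtends roughly a quarter
of the frame). Each frame also carries an *ideal* weight map — the
Gaussian-smoothed true mask — which serves as the informative-prior
reference in ablations. Per-patient sub-seeds are spawned from one master
seed, so corpora are reproducible and patients statistically independent.

Presets: **easy** (no shadows or defects, gentle speckle, slow drift) for
training studies; **hard** (shadows, faster drift, ~28% defect frames) for
filter and robustness studies.

What the phantoms do *not* capture: physical speckle correlation with
depth, refraction/reverberation artifacts, anatomy-shaped vessel trees,
probe-pressure deformation, annotation noise. Passing the phantom studies
therefore demonstrates that the pipeline is correctly wired and that the
architecture can exploit a good prior — not clinical-grade performance.

## Problem sizes used by the shipped tests and acceptance script

Full-scale training (256×256, 100 epochs, hundreds of clips) is a
GPU-scale job. The shipped studies run desk-scale versions chosen from a
CPU throughput benchmark, keeping the recipe (Adam, lr 1e-3, batch 16, no
augmentation, patient-level 8/1/3 split of 12 phantom patients) and
shrinking only frame side and schedule:

- memorisation check: one batch of 16 easy frames at 48×48, 300 steps;
- recovery study: 12 patients × 3 clips × 14 frames at 48×48 (336 train
  frames), 8 epochs;
- ablation: the same protocol retrained with uniform-random weight maps
  in place of the ideal ones.

One finding worth stating: on the easy preset the image alone suffices to
segment, so a *fully converged* model learns to ignore its prior —
swapping in a random map at inference then moves Dice by under 0.001, and
ideal- and random-prior training converge to the same plateau. The prior's
value shows mid-schedule, where it accelerates convergence strongly (at
the shipped 8-epoch schedule, held-out Dice 0.97 with ideal maps vs 0.81
with random maps). The ablation is therefore a statement about training
dynamics at desk scale, not about the converged easy-phantom model.

## Known limitations

- The connectedness term in the saliency QP is a graph-Laplacian
  surrogate, not the full neutrosophic-connectedness construction the
  prior literature describes; the precomputed-map bypass exists for users
  who need the original.
- Single-vessel (binary) heads only; multi-label segmentation is out of
  scope.
- The NumPy backend is single-device and optimises throughput only to the
  level needed for the shipped studies; it is not a general training
  framework.
- Gradient routing through 2×2 max pooling picks the first argmax on
  exact ties (ties are measure-zero for speckled inputs).
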