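# Methods

## The model

`lmsaunet` implements a lightweight U-shaped encoder–decoder for binary
skin-lesion segmentation. The classical U-Net stage — two dense 3×3
convolutions — is replaced everywhere by an **ECDF block** built around
depthwise-separable convolution and channel redundancy:

1. a bias-free pointwise (1×1) convolution compresses `C_in` channels to
   `C_out/N`, where the compression factor `N = 2^K` (default 8);
2. the compressed map is split into two halves of `C_out/(2N)` channels;
3. each half passes through a *sequential* cascade of `(N−2)/2` depthwise
   3×3 convolutions, and **every intermediate is kept**, so the block
   gathers features at growing receptive fields;
4. the compressed map plus all `(N−2)` saved maps are concatenated:
   `C_out/N + (N−2)·C_out/(2N) = C_out/2` channels, an identity that holds
   structurally for every valid configuration and is asserted in tests;
5. parallel **spatial–channel attention** gates the concatenated map:
   a spatial gate (per-pixel channel max/mean → 7×7 conv → sigmoid) and a
   channel gate (global average pool → adaptive 1-D conv of length
   `k = ⌊log2(C)/γ + b⌋_odd`, γ=2, b=1 → sigmoid), fused as
   `X · (α·ch + β·sp)` with learnable scalars α, β initialized at 0.5;
6. a final pointwise convolution fuses `C_out/2` back to `C_out`.

The network stacks four encoder stages (ECDF + 2×2 max pooling, channel
plan 64/128/256/512), then four decoder stages (parameter-free bicubic 2×
up-sampling, concatenation with the encoder skip in the order
`[upsampled, skip]`, ECDF), and a pointwise 64→2 classifier head. Input
spatial size must be divisible by 16. The decoder concatenation widths
under the default plan are 1024, 768, 384 and 192.

The two-channel head bridges to a single foreground probability via
`p = σ(logit_fg − logit_bg)`, which equals the two-class softmax entry;
masks threshold `p > 0.5` with ties going to background.

## Training objective and protocol

The loss is `L = α·L_BCE + β·L_IoU` with α = 0.25, β = 0.75. `L_BCE` is
the pixel-mean cross-entropy of the foreground probability (probabilities
clamped to `[1e−7, 1−1e−7]` inside the logs); `L_IoU` is one minus the
soft intersection-over-union with ε = 1e−6 guarding the divisor, summed
over all pixels of the batch.

Protocol defaults: AdamW with decoupled weight decay 1e−5 and conventional
moment coefficients (0.9, 0.999); cosine-annealed learning rate with
initial value 1e−6 (kept for protocol fidelity although it is atypically
small — every desk-scale run in this package overrides it to 1e−3, and the
CLI logs the override); optional warm restarts with period 64 epochs; at
most 200 epochs; early stopping when the validation loss fails to improve
for 20 consecutive epochs, restoring the best-validation parameters (ties
break to the earliest epoch); batch size 8; inputs resized to 256×256
(bilinear for images, nearest-neighbor for masks). Setting
`lr_min = lr_initial` degenerates the schedule to a constant rate; the
one-sample overfit check uses this because it probes raw optimizer
behavior, not the annealing protocol.

Evaluation is **micro-aggregated**: TP/FP/TN/FN pixel counts are pooled
over the whole set before Accuracy, per-class IoU, mean IoU, Dice and
frequency-weighted IoU are computed. The background class's IoU uses TN as
its true-positive count, and frequencies come from the ground truth. A
class absent from both prediction and truth has IoU 1 by convention so
empty masks evaluate cleanly. Per-class IoU and their mean are both
reported so either averaging convention can be read off.

## Parameter accounting and the lightness budget

All convolutions are bias-free, so the closed form `C_in·C_out·K²` holds
exactly, and the auditor (`count_parameters`, `estimate_macs`) reports
per-component counts that sum to the total. MACs are counted as
weight-count × output pixels per convolution; attention, pooling,
normalization and interpolation are counted by their arithmetic; one MAC
is two FLOPs, and both numbers are reported.

Two structural knobs are deliberate free choices, isolated in config and
visible in the audit report:

- **Normalization** (`norm: batch|none`): batch normalization + ReLU after
  the compression pointwise and after each depthwise convolution, nothing
  after the final fusion. Norm-free training diverges at desk scale, so
  `batch` is the default; its scalars are counted separately.
- **Fusion grouping** (`fusion_groups: 1|2`): the final pointwise
  `C_out/2 → C_out` can be dense or split into two channel groups. A fully
  dense fusion audits the whole default network at ≈ 0.477 M trainable
  scalars; with two groups it audits at ≈ 0.303 M. The design targets a
  sub-0.4 M parameter budget, so the grouped fusion is the default, and
  the ParamReport records the choice.

Parameter totals decrease strictly with N over {2, 4, 8, 16, 32} at fixed
architecture — the compression pointwise dominates, and its cost scales
as 1/N.

## Synthetic data

The generator emulates the disturbances dermoscopy suffers from without
requiring any download. Lesions are star-convex regions with radius
`r(θ) = r0·(1 + Σ a_k cos(kθ + φ_k))`, `Σ|a_k|` bounded below 1 so the
mask is one connected component; amplitudes are damped as 1/k so low
harmonics dominate, matching the smooth-but-irregular outlines of real
lesions. Defaults: 64×64 images, radius 0.15–0.30 of the side, 4
harmonics, total amplitude 0.25. Images are skin-toned background
(0.80, 0.60, 0.50) vs darker lesion fill (0.42, 0.28, 0.22) with ±0.04
color jitter, a linear illumination gradient up to 15 %, Gaussian pixel
noise σ = 0.02, then 0–4 dark curved hair strokes and 0–2 bright soft
bubbles. Artifacts perturb images only; masks are untouched, which is what
makes the pairs a fair robustness fixture.

What this does *not* emulate: pigment-network texture, multi-lesion
images, vignetting, specular glare, device color profiles, or ambiguous
boundaries. Passing the desk-scale learning checks therefore demonstrates
that the architecture, loss, and training loop optimize correctly — not
clinical-grade segmentation on real dermoscopy.

A master seed derives per-sample seeds through a counter-based
`SeedSequence` split, so any sample is independently reproducible and
dataset regeneration is byte-identical.

## Problem sizes for the desk-scale checks

The implementation is pure NumPy (a small reverse-mode autodiff tape with
BLAS-backed convolutions), so the package chooses CPU-friendly sizes for
its learning checks: a quarter-width channel plan (16/32/64/128,
`NetworkConfig.small()`, ≈ 0.021 M parameters) at 64×64 inputs. The full
Table-style plan is exercised by the audits and shape contracts at 256×256
and 64×64. The two learning checks are: overfitting one synthetic sample
to Dice ≥ 0.95 within 200 steps at fixed lr 1e−3, and training on 200
synthetic samples (160/40 split, ≤ 30 epochs, lr 1e−3) to held-out Dice
≥ 0.8 — the latter typically reaches ≈ 0.96.

## Numerical choices

- Correlation (not flipped-kernel) convention for all convolutions; zero
  same-padding; stride 1 everywhere except the 2×2 pooling.
- Bicubic up-sampling uses the Keys kernel (a = −0.5) at half-pixel-aligned
  sample centers with border taps clamped to the edge sample and rows
  normalized, so constants are reproduced exactly; it is a fixed linear
  operator (two small matrices per axis length) with an exact transpose
  for the gradient.
- The 1-D channel-attention convolution uses zero padding of ⌊k/2⌋; this
  is isolated behind the config should reflective padding ever be wanted.
- Weight initialization is fan-in-scaled normal, fully seeded; two
  networks built with the same seed are bit-identical.
- BatchNorm uses ε = 1e−5 and momentum 0.1; running statistics are
  serialized with checkpoints.
- Floating point is float32 for model state; the test suite checks
  gradients in float64 against central differences.

## Known limitations

- Single-device CPU training only; no augmentation, no multi-class heads,
  no boundary-distance metrics (Hausdorff/ASSD).
- Benchmark-grade scores on real dermoscopy collections (ISIC, PH²)
  require the external datasets and GPU-scale training and are out of
  scope; the desk-scale checks above are the package's substitutes.
- FLOP reporting conventions vary across the literature (MACs vs FLOPs,
  with or without attention arithmetic), so the auditor documents its
  convention (1 MAC = 2 FLOPs) and reports both counts.
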