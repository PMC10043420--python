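# Methods

## Problem setting

Minirhizotron frames show thin, bright root filaments crossing a textured
soil background. Two properties dominate the design: extreme class
imbalance (root pixels are typically 1–5 % of a frame) and domain shift
between soils (black meadow soil vs yellow-brown tidal soil, depending on
site and crop). The package frames the task as binary semantic
segmentation (0 = soil, 1 = root) and covers the full loop: annotation
I/O, model, loss, metrics, training, transfer, and synthetic data.

## Network

Two encoders share one decoder design.

* **Plain encoder** (baseline U-Net): five double-convolution stages
  (3×3, same padding, BatchNorm + ReLU) at strides 1/2/4/8/16 with widths
  64/128/256/512/1024 scaled by `base_width/64`. A 224×224 input yields
  pooled maps of 112/56/28/14 — the deepest map is 1/16 of the input.
* **ResNet50 encoder**: the standard stem (7×7/2) plus four bottleneck
  stages (3/4/6/3 blocks), tapped at strides 2/4/8/16/32 with widths
  64/256/512/1024/2048. Because the shallowest tap sits at stride 2, the
  decoder ends with one extra up-convolution block to restore full
  resolution. Pretrained encoder weights are deliberately not bundled;
  warm starting is done through the checkpoint/fine-tune path instead.

Each decoder stage is: 2×2 stride-2 transposed convolution (channels
reduced to the stage width), skip concatenation, optionally a PSA block,
then a double convolution. Inputs must be divisible by 32 — the ResNet
path needs it, and one uniform rule keeps the shape contract simple.

**PSA block.** Placed immediately after each skip concatenation, before
the stage's double convolution, in all four stages — attention then
arbitrates between encoder and decoder information. The C concatenated
channels are split into S=4 equal groups; branch i applies a grouped
convolution with kernel size {3,5,7,9} and group count {1,4,8,16}; each
branch output is scored by a squeeze-excitation head (global average pool
→ 1×1 bottleneck of width (C/S)/4 → ReLU → 1×1 expand); the S score
vectors are softmax-normalized across branches per channel slot and the
branches are rescaled before concatenation. These hyperparameters follow
the EPSANet design the attention module comes from. The channel
constraints (C divisible by S, C/S divisible by every group count) are
validated at build time with the offending stage named; narrow
configurations can pass reduced `psa_group_counts`.

BatchNorm follows every convolution (configurable momentum 0.9,
eps 1e-5). Upsampling is by transposed convolution, not interpolation.

## Loss

Per-class soft counts over a training batch of N pixels:
TP_p(c) = Σ p·g, FN_p(c) = Σ (1−p)·g, FP_p(c) = Σ p·(1−g), pooled over the
whole batch rather than per image. The Dice term is
C − Σ_c TP/(TP + α·FN + β·FP + ε) with α = β = 0.5 by default (recovering
classic soft Dice) and ε = 1e-6 guarding the denominator. A class absent
from both prediction and truth scores an overlap ratio of exactly 1, so a
perfect prediction gives 0 even on single-class batches.

The focal term has two modes. `canonical` (default) is
(1/N) Σ g(1−p)^γ(−log(p+ε)) with γ = 2. `as_printed` evaluates the bare
sum −(1/N) Σ g(1−p); this quantity is 0 at p = g and −1 at p = 1−g, i.e.
it *decreases* as predictions worsen, so minimizing it would drive
predictions away from the truth. It is kept for auditability only; the
canonical form is what training uses. The combined objective is
`dice + focal_weight × focal` with `focal_weight = 1`.

## Metrics

Hard confusion counts with root as the positive class; PA, IoU, precision,
recall, F1. Degenerate conventions: no positives anywhere → overlap
metrics are 1; truth has positives but a 0/0 precision or recall → that
component is 0. Dataset aggregation defaults to micro (pooled counts),
with macro (mean of per-image metrics) available. For binary masks
F1 = 2·IoU/(1+IoU) holds identically and is asserted to 1e-12 in tests.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999) with cosine annealing over the full run
(lr(e) = η_min + (lr₀−η_min)(1+cos(πe/E))/2, no warm restarts). The
reference protocol is batch 28, 100 epochs, lr₀ = 1e-4, data split 8:1:1
by largest-remainder apportionment under a fixed shuffle seed. No
augmentation is applied by default. Checkpoints carry weights, model
config, optimizer state, per-epoch history and provenance (seed, config
hash); the best-validation-IoU epoch is recorded. Images are centre
cropped/padded to the configured input size.

Because desk-scale batches are small, BatchNorm running statistics are
re-estimated by a cumulative-average pass over the training set before
each validation evaluation and before the final checkpoint — without this,
inference-mode predictions can collapse even when train-mode IoU is high.
When no validation set is supplied, the monitored metric is the
training-set IoU pooled from the training forward passes themselves.

Transfer learning warm-starts every weight from a source checkpoint after
a topology-compatibility check (encoder type, widths, attention
configuration, class count) and runs the same loop; the data-volume curve
fine-tunes on nested subsets (each extending the previous, under one
permutation seed) and evaluates on a fixed test set, reporting
epochs-to-stability, defined as the first epoch after which validation IoU
stays within 0.005 of its final value.

## Synthetic data

The generator emulates the features that matter for this task: root
centerlines are correlated random walks entering from a canvas edge
(heading perturbed by Gaussian steps), stamped with tapering widths;
branches spawn child walks at reduced width, so each primary root's
support is one connected component. The soil is band-limited Gaussian
noise (correlation length `texture_scale`) on a palette mean —
near-black for meadow soil, yellow-brown for tidal soil — plus a
low-frequency illumination ramp. Root pixels are brightened by at least
`root_brightness_offset` (70 grey levels by default, weighted toward red)
on the pre-blur intermediate, which is retained in the sample metadata so
the registration property is checkable. The mask is the exact filament
support before blur and sensor noise — no label noise. The foreground
fraction is controlled by rejection (up to 20 redraws, then an error
reporting the achieved fractions); per-sample seeds derive
deterministically from (master seed, index).

Defaults (256×256 canvas, 2 primary roots, widths 1.5–3.5 px) reproduce
the field's imbalance regime: about 80–90 % of samples carry < 5 % root
foreground. The generator does not model condensation, scratches,
reflections, or photorealistic soil texture, so passing tests demonstrate
correctness of the method's mechanics and its qualitative behaviour under
imbalance and domain shift — not field-data accuracy.

## Numerical engine

The networks run on a compact reverse-mode autodiff engine over float32
numpy arrays (`rhizoseg._autodiff`). Convolutions, transposed
convolutions and pooling are lowered to im2col/col2im with channels-last
memory layout so the gather/scatter phases move contiguous channel runs,
and the matrix products go through BLAS. The Adam update uses a fused
numba kernel. Every operator's gradient is verified against central
finite differences in the test suite, and the whole stack is
deterministic given seeds — there is no nondeterministic parallelism.

## Desk-scale profile

Tests and the acceptance script run the method end to end at reduced
problem sizes chosen as this package's development profile: 64×64 frames,
8-sample training sets, lr₀ = 1e-3, early stopping once the monitored IoU
reaches its target (0.95 for the overfit check, 0.90 for the transfer
comparison, budget 24 epochs). The overfit check asks the improved
network to reach training IoU ≥ 0.95 within 150 epochs; the transfer
check asks warm-started fine-tuning on the shifted soil domain to reach
IoU 0.90 in fewer epochs than training from scratch under the identical
budget. Full-scale settings (2000 images, batch 28, 100 epochs at 1e-4)
remain expressible through the same configs.

## Known limitations

* The synthetic domain is far easier than field imagery (no occlusion,
  condensation or annotation error); absolute metric values on it should
  not be read as field performance.
* Plain-encoder variants accept any `base_width`, but PSA's default
  grouping requires the default width; narrower models must adjust
  `psa_group_counts`.
* Checkpoints store the full optimizer state; for the 82M-parameter
  improved network that makes files of roughly a gigabyte.
* Only polygon and rectangle annotation shapes are supported; circles,
  polylines and points have no well-defined binary-mask semantics here
  and are rejected explicitly.
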