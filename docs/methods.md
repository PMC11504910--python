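# Methods

## Problem and scope

Lumbar spinal stenosis grading on MRI is treated as five independent binary
classification tasks (spinal canal stenosis, left/right neural foraminal
narrowing, left/right subarticular stenosis), each labelling an L4-L5 ROI
crop as normal/mild (0) or severe (1). This package implements the
classifier and its training/evaluation protocol and exercises them on
synthetic phantoms; it does not ship or train on clinical data, and it does
not attempt ROI localisation from whole-spine series.

## Numerical substrate

No deep-learning framework is used: `lssnet.autograd` is a reverse-mode
autodiff engine over numpy arrays (elementwise ops, broadcast-aware
backward, batched matmul, im2col convolution, depthwise convolution,
max/adaptive-average pooling, softmax/log-softmax), and `lssnet.nn` builds
the usual layers (Linear, Conv2d, BatchNorm2d, LayerNorm, Dropout) plus
Adam on top. Everything runs in float32 by default; the engine can be
switched to float64 (`set_default_dtype`), which the test suite uses for
finite-difference gradient checks and tight oracle comparisons. All
structured operations are verified against central differences and against
scipy's correlation.

## Architecture choices

The published description fixes the stage *types* (conv-BN-ReLU head with a
7×7 first kernel, max-pool, Enhanced Inception Modules from
depthwise-separable convolutions; CBAM / multi-head self-attention / slot
attention body; FC tail with LayerNorm and Dropout 0.5) but not depths or
widths. Choices made here, all exposed in `NetworkConfig`:

* Head: two conv stages (7×7 stride 2, 3×3 stride 2) then max-pool 3×3/2,
  then two EIMs — a 224×224 input reaches a 28×28 body map at the default
  strides. Default widths 32→64, EIM output 128.
* Channel attention computes `M_c = σ(FC₂(ReLU(FC₁(gap)) + ReLU(FC₁(gmp))))`
  — the two pooled paths share FC₁ and are summed *before* the single FC₂
  application. Reduction ratio r = 16 by default (unstated in the source
  description; the standard CBAM value). Spatial kernel 7×7, same-padded.
* MHSA: embedding dimension d = C and h = 4 heads by default; Q, K, V and
  the output map are learned linear projections of the flattened spatial
  tokens; per-head scaling 1/√(d/h).
* Slot attention: the pooling step before slot–token attention is
  ambiguous — pooling to one global token makes the attention structure
  degenerate. Default mode (`grid`) pools to a 7×7 token grid (adaptive
  average pooling, shrunk automatically for small maps) and projects each
  token to the slot width; `literal` mode pools to a single token exactly
  as written. Softmax is over the *slot* axis (slots compete for tokens),
  matching the published slot-attention convention. Slot update is a
  residual one-hidden-layer MLP (width = dim, ReLU); iters = 3; σ is kept
  nonnegative by a softplus parameterisation. Initial-slot noise is drawn
  only in training mode; evaluation uses S₀ = μ so that eval forward passes
  are deterministic.
* Branch fusion: concatenation of the branch summaries (GAP of the CBAM and
  MHSA maps; mean slot for SAM). Concatenation rather than summation keeps
  each branch's contribution dimensionally explicit, which makes the
  ablation bookkeeping (tail input width shrinking by exactly the removed
  branch's width) testable.
* Tail: FC → LayerNorm → ReLU → Dropout(0.5) → FC → ReLU → Dropout →
  FC(2) → softmax. A 2-way softmax is used rather than a single sigmoid to
  match the "probability distribution over classes" read-out.

`NetworkConfig.desk_scale()` narrows widths (head 8→16, body 32, slot dim
32, tail 64→32) and coarsens the stem (first-conv stride 4, giving a 14×14
body map) so that a full training run fits single-CPU minutes; the stage
structure, branch wiring, and 224×224 input contract are identical. The
stride choice was made for compute budget, measured at ~17× per-step
speedup, dominated by the (H·W)² self-attention matrix.

## Preprocessing and augmentation

* Min-max normalization to [0, 255] is per image (source intensities vary
  by device); constant images map to the lower bound. Idempotent.
* Bilinear resize to 224×224 uses half-pixel-centre coordinates so identity
  resize is exact; a 1×1 input degenerates to a constant fill.
* Demeaning subtracts per-channel means computed on the **training split
  only**, reused for held-out images (prevents leakage; the source protocol
  is silent). Optional division by the standard deviation is off by
  default, following the literal "demeaned" wording; a guard maps sd < 1e-8
  to 1.
* Augmentation order is fixed as scale → translate → rotate → vertical
  flip (composition is non-commutative and the order is unstated);
  parameters are uniform on [0.8, 1.2], [−20, 20] px, [−15°, 15°], flip
  probability 0.5 (the source says only "randomized"). Resampling is
  bilinear; exposed borders are constant-filled (0) with a reflect option.
  Both on-the-fly epoch augmentation and offline minority oversampling are
  provided, since the imbalance-mitigation mechanism is ambiguous.

## Training protocol

Adam (lr 0.001, β = 0.9/0.999, ε = 1e-8), 2-class cross-entropy (no class
weighting by default — imbalance handling is attributed to augmentation),
batch size 32 (16 in desk-scale runs), stratified 80:20 split. The 20% side
doubles as the early-stopping validation set, reproducing the published
protocol faithfully but leakily; `val_fraction` enables a separate
validation carve-out. Early stopping monitors validation loss with patience
10 by default (both unstated in the source); the best-epoch weights are
restored. Divergence (non-finite loss) aborts with a diagnostic. The whole
path — split, init, dropout, augmentation, slot noise — is driven by
explicit seeds; identical seeds give bit-identical splits and identical
final metrics.

The ablation harness trains seven models under one seed/split/schedule:
the full model, three minus-one variants, three only-one variants.

## Synthetic phantoms

Each phantom is a 224×224 image with a 12-bit-like intensity range
(background level 800, Gaussian texture sd 150, ceiling 4095 — deliberately
not 0–255 so normalization does real work). The canal analog is a
soft-edged bright ellipse (contrast 1500) centred with Gaussian jitter
(sd 4 px): mild images get semi-axes (28, 22.4) px, severe images (14, 8.4)
px — severity is a smaller, flatter sac, mimicking canal narrowing. Class
imbalance per lesion category uses the real frequency table
(`CONDITION_SEVERE_FRACTIONS`, e.g. 203/1632 severe for spinal stenosis).

What the phantoms do **not** emulate: anatomical context (vertebrae, discs,
nerve roots), multi-sequence appearance, device-dependent noise spectra,
partial-volume effects, or inter-reader label noise. A green end-to-end
test therefore establishes that the pipeline is correctly wired and can
learn a geometric severity cue — not that the architecture reaches any
particular clinical accuracy. Phantom separability is certified
independently of the network by a geometric threshold oracle (mean
intensity in the central disc), which reaches ≥95% accuracy by
construction of the default geometry.

## Numerical conventions and degenerate inputs

* Constant image under min-max normalization → all `normalize_lo`.
* Softmax subtracts the row max before exponentiation.
* Max reductions split gradient evenly across ties.
* Metrics with zero denominators (e.g. precision with no positive
  predictions) are reported as 0 and flagged in `MetricsReport.degenerate`.
* ROC thresholds: tied scores collapse to a single threshold; AUC is
  trapezoidal and equals the tie-aware Mann–Whitney statistic.
* Stratified splits force at least one member of each class on each side.
* BatchNorm uses running statistics in eval mode, so eval predictions are
  independent of batch composition.

## Known limitations

* DICOM input is not supported (no DICOM reader in the environment); the
  file interface is 16-bit PNG + CSV manifest.
* The engine is single-threaded numpy; training beyond desk scale (larger
  widths, 28×28 body maps, thousands of images) is possible but slow.
* The published headline numbers on the clinical dataset are out of scope
  here: they require the original multi-institution data and GPU-scale
  training. Nothing in this package asserts or reproduces them.
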