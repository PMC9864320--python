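# Methods

## Model and training procedure

The framework couples a segmentation network (SN) and an evaluation
network (EN) in a generator/discriminator arrangement specialized to
segmentation quality.

**SN.** A U-shaped encoder–decoder over `n_scales` resolution levels.
Each level is a *dense block*: `dense_block_depth` 3×3 conv+ReLU layers,
each consuming the concatenation of every earlier feature map in the
block and emitting `growth_rate` new channels; a 1×1 convolution then
compresses the concatenation before 2×2 average-pool downsampling (or,
on the decoder side, after nearest-neighbour upsampling and skip
concatenation). The head is a 1×1 convolution to 2 channels followed by
a per-pixel softmax, so the output is a probability map whose channels
sum to one everywhere. Inputs must be divisible by `2^n_scales`.

**EN.** A stack of `n_downsamples` stride-2 3×3 convolutions over the
5-channel concatenation of the image and a segmentation map, global
average pooling, one linear unit and a sigmoid — a single scalar
quality score per image. The published description leaves both
architectures' capacity open; all width/depth choices here are declared
configuration (`SegNetConfig`, `EvalNetConfig`), with a default profile
(< 500k SN parameters) and a `tiny()` profile used by the tests.

**Objectives.** Supervised loss = soft Dice (smoothing constant 1,
averaged over the two channels) + mean binary cross-entropy, unit
weights. The EN's discrimination loss labels (image, ground-truth) pairs
1 and (image, prediction) pairs 0, weighting predicted pairs by λl
(labeled) and λu (unlabeled); the real-pair term is unweighted. The
SN's adversarial term pushes both labeled and unlabeled predictions
toward EN score 1 and is added with weight λadv. Probabilities are
clamped to [1e-7, 1 − 1e-7] before any logarithm.

**Alternation and gradient isolation.** One EN update then one SN
update per step (1:1), on the same labeled batch and a fresh unlabeled
batch drawn with replacement. SN predictions are *detached* in the EN
loss; EN parameters are *frozen* in the adversarial term — freezing is
captured at graph-construction time in the autodiff engine, so no
ordering of `backward()` calls can leak gradients across the two
players. With λadv = λl = λu = 0 and an empty unlabeled pool the SSL
loop is bit-identical to continued supervised training under the same
seed (the labeled-batch stream is keyed by (seed, stream, epoch),
independent of phase).

**Optimizers.** SN: plain SGD, lr 0.001, weight decay 1e-4 (L2 folded
into the gradient). EN: Adam, lr 0.001, β = (0.9, 0.999). The source
description assigns SGD and Adam ambiguously; this assignment preserves
both printed settings and is configurable. The published scale (192×192
inputs, batch 16, 400 pretraining + 4000 co-training epochs) is exposed
as `TrainConfig.paper_scale()`.

## Desk-scale profile

`TrainConfig.tiny()`: 64×64 inputs, batch 8, 30 pretraining + 60
co-training epochs, SN with base 4 / growth 4 / depth 2 / 2 scales
(~8k parameters), EN with base 4 / 3 downsamples (~1.7k). One deviation
matters: **the tiny profile raises the SN learning rate to 0.05.** At
lr 0.001, plain SGD on tens of images for tens of epochs never escapes
the all-background solution (the supervised loss falls by ~0.004 per 30
epochs and test DSC stays exactly 0) — the published rate is tuned for
thousands of epochs on thousands of images. A sweep showed 0.01 still
collapsed, 0.05 learned stably (~60 DSC in 30 epochs), 0.1 was
unstable, 0.2 diverged; 0.05 was fixed once and kept. The default
`TrainConfig()` retains lr 0.001.

## Synthetic phantoms

`PhantomConfig` describes the generative world: a mucosa-pink base
color with coarse-grid low-frequency shading, 1–2 lesions per image
(defaults), each a rotated ellipse (minor/major ratio 0.6–1.0) whose
boundary radius is modulated by 3–6 random cosine harmonics with total
amplitude ≤ 0.25 — irregular enough that Hausdorff distances are
informative. Lesions shift color darker/redder with magnitude
max(0.15, 2.5·noise SD), guaranteeing class contrast at least 2.5× the
pixel noise (SD 0.04 by default) so a small network can learn the task.
Optional specular highlight disks (probability 0.3) and a radial
vignette (strength 0.25) mimic endoscope artifacts. The mask is exactly
the generative lesion support; no morphology is applied, and total
lesion fraction is capped below 0.6 by skipping lesions that would
exceed it.

Randomness is hierarchical: each sample's generator is seeded by
(seed, role, index), so enlarging the test pool never changes a
training image. What the phantoms do **not** model: real mucosal
texture statistics, vendor color profiles, motion blur, bubbles,
instruments, and ambiguous lesion boundaries. A green test here
establishes that the machinery (losses, alternation, metrics,
reproducibility) is correct — not that the method reaches clinical
accuracy.

## Numerical and reporting choices

* All network arithmetic is float32 (parameters and batches); losses
  accept float64 arrays for closed-form checks. The autodiff engine
  preserves input dtype.
* Prediction binarization is argmax over the two channels (equivalent
  to thresholding the lesion probability at 0.5).
* Contours: foreground pixels with a background 4-neighbour, the image
  border counting as background. Hausdorff distances are reported in
  pixels — the source tables print "mm" but provide no pixel spacing,
  so physical units are unrealizable.
* Zero-denominator conventions (logged per image in `MetricsReport.notes`):
  both masks empty → all overlap metrics 100%; empty prediction with
  non-empty ground truth → precision 0; the converse → recall 0; a
  Hausdorff distance against an empty contour is NaN and excluded from
  aggregates.
* Aggregates are mean ± sample SD (n−1; a single image reports SD 0).
* `run_protocol`'s supervised baseline is an *equal-budget* arm: the
  shared pretrained model continues purely supervised training for the
  same number of epochs as the SSL arms (implemented as co-training
  with all loss weights zero, which is provably identical). Comparing
  the SSL arms against the pretrained model alone would conflate the
  adversarial contribution with simply training longer.
* Degenerate empty-lesion phantoms, empty unlabeled pools and empty
  batches are all defined behavior; empty *labeled* pools are errors.

## Known limitations

* At desk scale the adversarial term's influence on the SN
  (λadv·λu = 0.005 of the loss for unlabeled data, ~120 update steps)
  is below between-seed noise: the 5-seed protocol grid shows arm
  differences of ±0.5 DSC against seed-to-seed spreads of tens of DSC
  points, so the growing-unlabeled-pool benefit reported at full scale
  (thousands of epochs, thousands of images) is not resolvable here,
  and one in five phantom worlds fails to leave the all-background
  optimum within the 30-epoch pretraining budget.
* The EN emits a single global score; it cannot localize *where* a
  segmentation is implausible.
* Convolutions are hand-written numpy (shift-and-add / batched matmul);
  they are adequate for 64×64 batches but not for the published
  192×192 × 4000-epoch regime.
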