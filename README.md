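# lesionseg

Adversarial semi-supervised segmentation of gastrointestinal lesions in
endoscopic images — at desk scale, on synthetic phantoms, with no GPU
and no clinical data required.

## The problem

Pixel-accurate lesion annotation of endoscopic frames is expensive:
clinics accumulate thousands of images but gastroenterologists can mask
only a small fraction of them. This package implements a generative-
adversarial semi-supervised training scheme for that regime. Two
networks are trained against each other:

* **SN (segmentation network)** — a densely connected U-shaped
  encoder–decoder mapping an RGB frame to a two-channel per-pixel
  probability map Ŷ (background / lesion, softmax).
* **EN (evaluation network)** — a discriminator that receives an image
  concatenated with a segmentation map (5 input channels) and emits one
  sigmoid quality score; it is trained to score physician ground-truth
  pairs high and SN predictions low.

Training proceeds in two phases. Supervised pretraining minimizes, on
labeled images X_l with ground truth Y_l,

    L_seg(X_l, Y_l; θS) = L_dice(Seg(X_l), Y_l) + L_bce(Seg(X_l), Y_l).

Adversarial co-training then alternates every step: the EN minimizes

    l_E = bce(Ev(X_l, Y_l), 1) + λl·bce(Ev(X_l, Seg(X_l)), 0)
                               + λu·bce(Ev(X_u, Seg(X_u)), 0)

with SN predictions detached, and the SN minimizes

    l_S = L_seg + λadv·l_adv,
    l_adv = λl·bce(Ev(X_l, Seg(X_l)), 1) + λu·bce(Ev(X_u, Seg(X_u)), 1)

with θE frozen. The unlabeled pool X_u enters only through l_adv: the
SN is pushed to produce maps the EN cannot tell from ground truth, on
images nobody annotated. Evaluation uses the five standard pixel-level
metrics — DSC, IoU, precision, recall (percentages from TP/FP/FN
counts) and the symmetric Hausdorff distance between mask contours (in
pixels).

Everything runs on **synthetic lesion phantoms**: pinkish textured
backgrounds with radially perturbed elliptical lesions, specular
highlights and vignetting, plus exact generative masks. The whole
pipeline — including the networks and backpropagation — is plain
numpy/scipy; no deep-learning framework is needed.

## Worked example

```python
import lesionseg as ls

split  = ls.generate_split(ls.PhantomConfig(n_labeled=10, n_unlabeled=50,
                                            n_test=20, seed=0))
config = ls.TrainConfig.tiny(seed=0, val_every=0)
pre    = ls.pretrain(split, config)          # phase 1: supervised
state  = ls.train_ssl(split, pre, config)    # phase 2: adversarial
report = ls.evaluate(ls.predict(state, split.test),
                     [s.mask for s in split.test])
print(report.summary())
```

Output (one CPU, ~1 minute):

```
final epoch: l_seg=0.2743  l_adv=2.4664  l_S=0.2989  l_E=1.0425
EN score, ground-truth mask: 0.885
EN score, random mask:       0.322
test metrics after co-training: DSC = 88.15 ± 8.17, IOU = 79.60 ± 11.44,
PRE = 94.79 ± 4.51, REC = 83.51 ± 12.24, HDIST = 14.20 ± 11.00
```

Reading the numbers: `l_S = l_seg + 0.01·l_adv` is the SN objective;
the EN score gap (0.885 vs 0.322) shows the discriminator has learned
what a plausible lesion mask looks like; DSC/IoU are overlap
percentages against the held-out ground truth, and HDIST is the
worst-case boundary error in pixels (lower is better). The
`examples/` directory has one short script per capability: phantom
simulation, preprocessing, supervised training, adversarial
co-training, metric computation, and the fixed-labeled /
growing-unlabeled experiment grid (`run_protocol`).

Real datasets are consumed from the conventional directory layout
(`<split>/images/*.png|jpg` + `<split>/masks/...`, stems matching) via
`ls.build_split(...)`; `ls.preprocess(...)` applies border cropping and
the 192×192 working-resolution resize. `TrainConfig.paper_scale()`
exposes the published full-scale settings (batch 16, thousands of
epochs); tests and examples use the desk-scale `TrainConfig.tiny()`
profile.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — generates a seeded phantom
split, pretrains the SN, runs adversarial co-training, and prints the
five test-set metrics to stderr — then writes the results file.
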