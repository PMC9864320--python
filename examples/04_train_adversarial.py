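"""Adversarial semi-supervised co-training with unlabeled images.

Phase 2: the pretrained SN trains against the evaluation network (EN).
Each step the EN learns to score ground-truth pairs high and predicted
pairs low, then the SN is nudged (weight λadv) toward predictions the
EN mistakes for ground truth — on labeled AND unlabeled images, which
is how the unlabeled pool contributes.
"""

import numpy as np

import lesionseg as ls

split = ls.generate_split(ls.PhantomConfig(
    n_labeled=10, n_unlabeled=50, n_test=20, seed=0))
config = ls.TrainConfig.tiny(seed=0, val_every=0)

pre = ls.pretrain(split, config)
state = ls.train_ssl(split, pre, config)
h = state.history[-1]
print(f"final epoch: l_seg={h['l_seg']:.4f}  l_adv={h['l_adv']:.4f}  "
      f"l_S={h['l_S']:.4f}  l_E={h['l_E']:.4f}")

# the EN should now distinguish real annotations from garbage
rng = np.random.default_rng(0)
s = split.test[0]
gt_score = ls.ev_forward(state.en, s.image, ls.mask_to_map(s.mask))
random_mask = (rng.uniform(size=s.mask.shape) < s.mask.mean()).astype("uint8")
rnd_score = ls.ev_forward(state.en, s.image, ls.mask_to_map(random_mask))
print(f"EN score, ground-truth mask: {gt_score:.3f}")
print(f"EN score, random mask:       {rnd_score:.3f}")

report = ls.evaluate(ls.predict(state, split.test),
                     [s.mask for s in split.test])
print(f"test metrics after co-training: {report.summary()}")
# l_S = l_seg + λadv*l_adv is the SN objective; the EN score gap shows
# the discriminator has learned what a plausible segmentation looks like.
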