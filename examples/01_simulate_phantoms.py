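"""Generate a synthetic endoscopic phantom dataset on disk.

Creates a labeled / unlabeled / test split of lesion phantoms and writes
it in the standard directory layout (`<split>/images`, `<split>/masks`),
the same shape real endoscopic datasets ship in.
"""

from pathlib import Path

import lesionseg as ls

config = ls.PhantomConfig(n_labeled=8, n_unlabeled=16, n_test=4,
                          image_size=(64, 64), seed=42)
split = ls.generate_split(config)
root = ls.write_split(split, Path("scratch_phantoms"))

print(f"split sizes (labeled, unlabeled, test): {split.sizes()}")
fractions = [s.mask.mean() for s in split.labeled]
print(f"lesion pixel fraction across labeled images: "
      f"min {min(fractions):.3f}, max {max(fractions):.3f}")
print(f"written under {root}/: labeled/, unlabeled/, test/")
# The fractions tell you how much of each frame is lesion; phantoms keep
# this well below 0.6 so the background class always dominates, as in
# real endoscopy. A fixed seed makes the dataset byte-reproducible.
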