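"""Load an image/mask pair from disk and apply standard preprocessing.

Heterogeneous endoscopic datasets (384x384 up to 1920x1080 frames) are
all brought to one square working resolution; masks are binarized at
half dynamic range so JPEG gray ringing disappears.
"""

from pathlib import Path

import lesionseg as ls

root = Path("scratch_phantoms")
if not root.exists():            # build the demo dataset if needed
    ls.write_split(ls.generate_split(ls.PhantomConfig(
        n_labeled=2, n_unlabeled=0, n_test=0, seed=42)), root)

img = sorted((root / "labeled" / "images").iterdir())[0]
mask = root / "labeled" / "masks" / img.name
sample = ls.load_sample(img, mask)
print(f"loaded '{sample.source_id}': image {sample.image.shape}, "
      f"mask values {sorted(set(sample.mask.ravel().tolist()))}")

out = ls.preprocess(sample, target_size=(192, 192), crop_margin=0.05,
                    trim_black_border=True)
print(f"after preprocessing: image {out.image.shape}, "
      f"mask still binary: {set(out.mask.ravel().tolist()) <= {0, 1}}")
# 192x192 is the published working resolution; the 5% margin crop mimics
# removing uninformative frame borders before resizing.
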