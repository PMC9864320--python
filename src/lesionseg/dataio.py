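"""Image/mask I/O, preprocessing and dataset assembly.

Endoscopic lesion datasets ship as RGB frames (JPEG or PNG) with
physician-drawn binary masks stored as black-and-white images.  This
module loads such pairs into :class:`ImageSample`, applies the standard
preprocessing (optional border/artifact cropping, resize to a fixed
square, PNG conversion) and assembles labeled/unlabeled/test
:class:`DatasetSplit` objects from a directory layout of the form::

    <split>/images/*.png|jpg
    <split>/masks/*.png|jpg      (matching filename stems)

Masks are binarized at half dynamic range on load (JPEG compression
leaves gray ringing around edges), images are scaled to [0, 1], and all
resizing uses bilinear interpolation for images but nearest-neighbour
for masks so binarity survives every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .errors import InputError, ValidationError

__all__ = ["ImageSample", "DatasetSplit", "load_sample", "preprocess",
           "save_png", "write_split", "build_split"]

_IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass
class ImageSample:
    """One endoscopic frame with an optional binary lesion mask.

    ``image`` is H×W×3 float in [0, 1]; ``mask`` (if present) is H×W
    with values exactly {0, 1}, 1 marking lesion pixels.  Unlabeled
    samples carry no mask by definition.
    """

    image: np.ndarray
    mask: Optional[np.ndarray] = None
    is_labeled: bool = False
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValidationError(
                f"image must be HxWx3, got shape {self.image.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValidationError(
                    f"mask shape {self.mask.shape} does not match image "
                    f"shape {self.image.shape[:2]} for '{self.source_id}'")
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(
                    f"mask for '{self.source_id}' is not binary "
                    f"(values {vals[:5]}...)")
            self.mask = self.mask.astype(np.uint8)
        if not self.is_labeled and self.mask is not None:
            raise ValidationError(
                f"unlabeled sample '{self.source_id}' must not carry a mask")

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass
class DatasetSplit:
    """Labeled / unlabeled / test pools with disjoint source ids."""

    labeled: list = field(default_factory=list)
    unlabeled: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def __post_init__(self):
        ids = [s.source_id for pool in (self.labeled, self.unlabeled,
                                        self.test) for s in pool]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(
                f"source ids shared across pools: {sorted(dupes)}")
        for name, pool in (("labeled", self.labeled), ("test", self.test)):
            missing = [s.source_id for s in pool if s.mask is None]
            if missing:
                raise ValidationError(
                    f"{name} samples without masks: {missing}")
        for s in self.unlabeled:
            if s.is_labeled:
                raise ValidationError(
                    f"unlabeled pool contains labeled sample '{s.source_id}'")

    def sizes(self) -> tuple:
        return (len(self.labeled), len(self.unlabeled), len(self.test))


# ---------------------------------------------------------------------
# loading / saving

def _read_image(path) -> Image.Image:
    try:
        return Image.open(path)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read image file '{path}': {exc}") from exc


def load_sample(image_path, mask_path=None, source_id: str | None = None
                ) -> ImageSample:
    """Load an RGB image (and optional mask) into an :class:`ImageSample`.

    The image is scaled to [0, 1].  The mask is converted to grayscale
    and binarized by thresholding at 0.5 of full range, so JPEG gray
    ringing collapses to clean {0, 1} labels.
    """
    image_path = Path(image_path)
    img = np.asarray(_read_image(image_path).convert("RGB"),
                     dtype=np.float64) / 255.0
    mask = None
    if mask_path is not None:
        gray = np.asarray(_read_image(Path(mask_path)).convert("L"),
                          dtype=np.float64) / 255.0
        mask = (gray >= 0.5).astype(np.uint8)
        if mask.shape != img.shape[:2]:
            raise ValidationError(
                f"mask '{mask_path}' shape {mask.shape} does not match "
                f"image '{image_path}' shape {img.shape[:2]}")
    return ImageSample(image=img, mask=mask, is_labeled=mask is not None,
                       source_id=source_id or image_path.stem)


def _trim_black_border(image: np.ndarray, mask, threshold: float = 0.02):
    """Drop outer rows/columns whose mean intensity is below `threshold`.

    Endoscope frames typically have a dark circular vignette border;
    trimming is restricted to contiguous runs at the edges.
    """
    row_mean = image.mean(axis=(1, 2))
    col_mean = image.mean(axis=(0, 2))

    def run(means):
        lo = 0
        while lo < len(means) - 1 and means[lo] < threshold:
            lo += 1
        hi = len(means)
        while hi > lo + 1 and means[hi - 1] < threshold:
            hi -= 1
        return lo, hi

    r0, r1 = run(row_mean)
    c0, c1 = run(col_mean)
    image = image[r0:r1, c0:c1]
    if mask is not None:
        mask = mask[r0:r1, c0:c1]
    return image, mask


def preprocess(sample: ImageSample, target_size=(192, 192),
               crop_margin: float = 0.0,
               trim_black_border: bool = False) -> ImageSample:
    """Center-crop, optionally trim dark borders, and resize.

    Follows the standard preparation for heterogeneous endoscopic
    datasets: remove uninformative frame borders, then resize everything
    to one square working resolution (192×192 at full scale).  Bilinear
    for the image, nearest-neighbour for the mask.  Returns a new
    sample; the input is never modified.
    """
    th, tw = int(target_size[0]), int(target_size[1])
    if th < 16 or tw < 16:
        raise ValidationError(f"target_size must be >= (16, 16), got {target_size}")
    if not 0.0 <= crop_margin < 0.5:
        raise ValidationError(f"crop_margin must be in [0, 0.5), got {crop_margin}")

    image = sample.image
    mask = sample.mask
    if trim_black_border:
        image, mask = _trim_black_border(image, mask)
    h, w = image.shape[:2]
    dy, dx = int(round(h * crop_margin)), int(round(w * crop_margin))
    if h - 2 * dy < 1 or w - 2 * dx < 1:
        raise ValidationError(
            f"crop_margin {crop_margin} leaves no pixels in a {h}x{w} image")
    image = image[dy:h - dy, dx:w - dx]
    if mask is not None:
        mask = mask[dy:h - dy, dx:w - dx]

    if image.shape[:2] != (th, tw):
        image = _sk_resize(image, (th, tw), order=1, mode="reflect",
                           anti_aliasing=False, preserve_range=True)
        if mask is not None:
            mask = _sk_resize(mask, (th, tw), order=0, mode="edge",
                              anti_aliasing=False,
                              preserve_range=True).astype(np.uint8)
    image = np.clip(image, 0.0, 1.0)
    return replace(sample, image=image, mask=mask)


def save_png(sample: ImageSample, out_dir) -> list:
    """Write the sample as 8-bit PNG under ``out_dir/images`` (+ ``masks``).

    The mask round-trips losslessly ({0,1} ↔ {0,255}); the image is
    quantized to 8 bits so a reload agrees within 1/255 per channel.
    Returns the written paths (one or two).
    """
    out_dir = Path(out_dir)
    paths = []
    try:
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        img8 = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
        img_path = img_dir / f"{sample.source_id}.png"
        Image.fromarray(img8, mode="RGB").save(img_path)
        paths.append(img_path)
        if sample.mask is not None:
            mask_dir = out_dir / "masks"
            mask_dir.mkdir(parents=True, exist_ok=True)
            mask_path = mask_dir / f"{sample.source_id}.png"
            Image.fromarray((sample.mask * 255).astype(np.uint8),
                            mode="L").save(mask_path)
            paths.append(mask_path)
    except OSError as exc:
        raise InputError(f"cannot write under '{out_dir}': {exc}") from exc
    return paths


def write_split(split: DatasetSplit, root) -> Path:
    """Materialize a split as ``root/{labeled,unlabeled,test}/...`` PNGs."""
    root = Path(root)
    for name, pool in (("labeled", split.labeled),
                       ("unlabeled", split.unlabeled),
                       ("test", split.test)):
        for s in pool:
            save_png(s, root / name)
        (root / name / "images").mkdir(parents=True, exist_ok=True)
    return root


# ---------------------------------------------------------------------
# dataset assembly

def _list_images(d: Path) -> dict:
    if not d.is_dir():
        return {}
    out = {}
    for p in sorted(d.iterdir()):
        if p.suffix.lower() in _IMAGE_EXTS:
            if p.stem in out:
                raise ValidationError(
                    f"duplicate stem '{p.stem}' in {d} "
                    f"({out[p.stem].name} vs {p.name})")
            out[p.stem] = p
    return out


def _load_dir(split_dir: Path, require_masks: bool, labeled: bool) -> list:
    images = _list_images(split_dir / "images")
    masks = _list_images(split_dir / "masks")
    if require_masks:
        missing = sorted(set(images) - set(masks))
        if missing:
            raise ValidationError(
                f"images without matching masks in {split_dir}: {missing}")
    samples = []
    for stem in sorted(images):
        mask_path = masks.get(stem) if require_masks else None
        samples.append(load_sample(images[stem], mask_path, source_id=stem))
    return samples


def build_split(labeled_dir, unlabeled_dir, test_dir) -> DatasetSplit:
    """Assemble a :class:`DatasetSplit` from three directories.

    ``labeled_dir`` and ``test_dir`` must contain image/mask pairs
    matched by filename stem; ``unlabeled_dir`` contains images only.
    Ordering is deterministic (sorted by source id) and the split
    invariants (disjoint ids, masks where required) are enforced.
    """
    return DatasetSplit(
        labeled=_load_dir(Path(labeled_dir), require_masks=True, labeled=True),
        unlabeled=_load_dir(Path(unlabeled_dir), require_masks=False,
                            labeled=False),
        test=_load_dir(Path(test_dir), require_masks=True, labeled=True),
    )
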