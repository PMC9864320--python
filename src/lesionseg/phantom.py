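"""Synthetic endoscopic lesion phantoms with exact ground-truth masks.

Real endoscopic lesion datasets are private or large; every experiment
in this package can instead run on phantoms: a smooth pinkish mucosa
background with low-frequency shading, one or more lesion-like regions
(radially perturbed ellipses with a distinct color shift), optional
specular highlight disks, pixel noise and a radial vignette.  The mask
is exactly the generative lesion support — no morphology is applied —
so metrics computed against it are exact by construction.

Reproducibility: a single integer seed drives per-sample substreams
keyed by (seed, role, index), so e.g. enlarging the test set never
changes the training images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .dataio import DatasetSplit, ImageSample
from .errors import ValidationError

__all__ = ["PhantomConfig", "generate_phantom", "generate_split"]

_ROLE_IDS = {"labeled": 0, "unlabeled": 1, "test": 2}


@dataclass
class PhantomConfig:
    """Parameters of the phantom world.

    Defaults describe the desk-scale split used throughout the tests:
    10 labeled / 200 unlabeled / 50 test images of 64×64 pixels, one or
    two lesions per image occupying roughly 10–30% of the image width in
    radius.  ``texture_noise_sd`` is the pixel-noise SD in intensity
    units; the lesion color shift is kept at least 2.5× larger so the
    task stays learnable by a small network.
    """

    n_labeled: int = 10
    n_unlabeled: int = 200
    n_test: int = 50
    image_size: tuple = (64, 64)
    lesion_count_range: tuple = (1, 2)
    lesion_radius_range: tuple = (0.12, 0.28)
    texture_noise_sd: float = 0.04
    specular_prob: float = 0.3
    vignette_strength: float = 0.25
    seed: int = 0

    def validate(self):
        if min(self.n_labeled, self.n_unlabeled, self.n_test) < 0:
            raise ValidationError("sample counts must be >= 0")
        lo, hi = self.lesion_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValidationError(
                f"lesion_radius_range must lie in (0, 0.5), got {self.lesion_radius_range}")
        c0, c1 = self.lesion_count_range
        if c0 < 0 or c1 < c0:
            raise ValidationError(
                f"invalid lesion_count_range {self.lesion_count_range}")
        if not 0.0 <= self.specular_prob <= 1.0:
            raise ValidationError("specular_prob must be in [0, 1]")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValidationError("vignette_strength must be in [0, 1)")
        if self.texture_noise_sd < 0:
            raise ValidationError("texture_noise_sd must be >= 0")
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValidationError("image_size must be at least 16x16")


def _low_freq_field(rng, shape, cells: int = 6, amplitude: float = 0.08):
    """Smooth per-channel shading: coarse gaussian grid upsampled bilinearly."""
    coarse = rng.normal(0.0, 1.0, size=(cells, cells, shape[2]))
    field = _sk_resize(coarse, shape, order=1, mode="reflect",
                       anti_aliasing=False, preserve_range=True)
    return amplitude * field


def _lesion_support(rng, h, w, radius_frac):
    """Boolean support of one radially perturbed ellipse.

    The boundary radius is r(θ) = 1 + Σ_k a_k cos(kθ + φ_k) over 3–6
    harmonics with total amplitude ≤ 0.25, which keeps the area within
    a factor ~2 of the unperturbed ellipse while making the contour
    irregular enough for boundary metrics to be informative.
    """
    r_pix = radius_frac * w
    margin = radius_frac * 1.3
    cy = rng.uniform(margin, 1 - margin) * h
    cx = rng.uniform(margin, 1 - margin) * w
    b_ratio = rng.uniform(0.6, 1.0)
    angle = rng.uniform(0, np.pi)
    n_harm = int(rng.integers(3, 7))
    amps = rng.uniform(0.0, 0.25 / n_harm, size=n_harm)
    phases = rng.uniform(0, 2 * np.pi, size=n_harm)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    rho = np.sqrt((u / r_pix) ** 2 + (v / (r_pix * b_ratio)) ** 2)
    theta = np.arctan2(v, u)
    boundary = 1.0 + sum(a * np.cos((k + 1) * theta + p)
                         for k, (a, p) in enumerate(zip(amps, phases)))
    return rho <= boundary


def generate_phantom(config: PhantomConfig, rng: np.random.Generator,
                     source_id: str = "phantom", labeled: bool = True
                     ) -> ImageSample:
    """Draw one phantom image + mask from the configured world."""
    config.validate()
    h, w = config.image_size
    base = np.array([0.62, 0.38, 0.33])                     # mucosa pink
    image = base[None, None, :] + _low_freq_field(rng, (h, w, 3))

    mask = np.zeros((h, w), dtype=bool)
    n_lesions = int(rng.integers(config.lesion_count_range[0],
                                 config.lesion_count_range[1] + 1))
    # Lesion color shift: darker and redder than mucosa, magnitude bounded
    # below at max(0.15, 2.5*noise_sd) to keep contrast >= 2x noise SD.
    shift_mag = max(0.15, 2.5 * config.texture_noise_sd)
    for _ in range(n_lesions):
        radius = rng.uniform(*config.lesion_radius_range)
        support = _lesion_support(rng, h, w, radius)
        if mask.mean() + support.mean() > 0.6:              # fraction cap
            continue
        mask |= support
        shift = shift_mag * np.array([rng.uniform(0.4, 1.0),
                                      -rng.uniform(0.8, 1.2),
                                      -rng.uniform(0.3, 0.8)])
        image[support] += shift[None, :]

    if rng.uniform() < config.specular_prob:
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(int(rng.integers(1, 4))):
            sy, sx = rng.uniform(0, h), rng.uniform(0, w)
            sr = rng.uniform(1.0, max(1.5, 0.04 * w))
            disk = (yy - sy) ** 2 + (xx - sx) ** 2 <= sr ** 2
            image[disk] = 0.95

    if config.texture_noise_sd > 0:
        image += rng.normal(0.0, config.texture_noise_sd, size=image.shape)

    if config.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
        image *= (1.0 - config.vignette_strength * d2 / 2.0)[:, :, None]

    image = np.clip(image, 0.0, 1.0)
    mask_u8 = mask.astype(np.uint8)
    return ImageSample(image=image,
                       mask=mask_u8 if labeled else None,
                       is_labeled=labeled,
                       source_id=source_id)


def _sample_rng(seed: int, role: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), _ROLE_IDS[role], index)))


def generate_split(config: PhantomConfig, return_hidden_masks: bool = False):
    """Generate a full labeled/unlabeled/test split of phantoms.

    Unlabeled samples discard their ground truth (that is what makes
    them unlabeled); pass ``return_hidden_masks=True`` to additionally
    receive ``{source_id: mask}`` for the unlabeled pool, which lets
    experiments quantify how much the unlabeled data actually helped.
    """
    config.validate()
    pools = {}
    hidden = {}
    for role, n in (("labeled", config.n_labeled),
                    ("unlabeled", config.n_unlabeled),
                    ("test", config.n_test)):
        samples = []
        for i in range(n):
            rng = _sample_rng(config.seed, role, i)
            sid = f"{role}_{i:04d}"
            s = generate_phantom(config, rng, source_id=sid, labeled=True)
            if role == "unlabeled":
                hidden[sid] = s.mask
                s = ImageSample(image=s.image, mask=None, is_labeled=False,
                                source_id=sid)
            samples.append(s)
        pools[role] = samples
    split = DatasetSplit(labeled=pools["labeled"],
                         unlabeled=pools["unlabeled"], test=pools["test"])
    if return_hidden_masks:
        return split, hidden
    return split
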