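"""The segmentation network (SN) and evaluation network (EN).

SN is a U-shaped, densely connected encoder–decoder: at every scale a
dense block (each 3×3 conv layer sees the concatenation of all earlier
features in the block) is followed by a 1×1 compression; downsampling
is 2×2 average pooling, upsampling nearest-neighbour with skip
concatenation.  The head is a 1×1 conv + softmax producing a
two-channel (background/lesion) probability map at input resolution.

EN is the adversary: it consumes the image concatenated with a
two-channel segmentation map (5 input channels), applies a stack of
stride-2 convolutions, global-average-pools and emits one sigmoid
quality score per image — trained to score ground-truth pairs high and
predicted pairs low.

Capacity knobs (channels, depth, scales) are configuration, not
architecture: all contracts hold for any setting, and the defaults keep
the SN under 500k parameters so everything trains on one CPU.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ValidationError

__all__ = ["SegNetConfig", "EvalNetConfig", "SegmentationNetwork",
           "EvaluationNetwork", "PredictionMap", "seg_forward", "ev_forward",
           "mask_to_map", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SegNetConfig:
    base_channels: int = 8
    dense_block_depth: int = 3
    growth_rate: int = 8
    n_scales: int = 3

    @classmethod
    def tiny(cls) -> "SegNetConfig":
        """Smallest config that still learns the phantom task."""
        return cls(base_channels=4, dense_block_depth=2, growth_rate=4,
                   n_scales=2)


@dataclass(frozen=True)
class EvalNetConfig:
    base_channels: int = 8
    n_downsamples: int = 4

    @classmethod
    def tiny(cls) -> "EvalNetConfig":
        return cls(base_channels=4, n_downsamples=3)


# ---------------------------------------------------------------------
# layers

class _Conv:
    """3x3 or 1x1 conv with He-normal init."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1, dtype=np.float32):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.w = Tensor(w.astype(dtype), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=self.stride,
                         padding=self.pad)

    @property
    def params(self):
        return [self.w, self.b]


class _DenseBlock:
    """Each layer concatenates all previous features within the block."""

    def __init__(self, rng, c_in, depth, growth, dtype=np.float32):
        self.convs = []
        c = c_in
        for _ in range(depth):
            self.convs.append(_Conv(rng, c, growth, k=3, dtype=dtype))
            c += growth
        self.c_out = c

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv in self.convs:
            y = ad.relu(conv(ad.concat(feats, axis=1) if len(feats) > 1
                             else feats[0]))
            feats.append(y)
        return ad.concat(feats, axis=1)

    @property
    def params(self):
        return [p for c in self.convs for p in c.params]


class _Module:
    """Shared parameter plumbing for the two networks."""

    def __init__(self):
        self._params: list = []

    @property
    def parameters(self) -> list:
        return self._params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params))

    def state_arrays(self) -> list:
        return [p.data.copy() for p in self._params]

    def load_state_arrays(self, arrays):
        if len(arrays) != len(self._params):
            raise ValidationError(
                f"checkpoint has {len(arrays)} arrays, network expects "
                f"{len(self._params)}")
        for p, a in zip(self._params, arrays):
            if p.data.shape != a.shape:
                raise ValidationError(
                    f"parameter shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=p.data.dtype)

    def param_digest(self) -> str:
        """Hash of all parameter bytes; used to assert gradient isolation."""
        import hashlib
        h = hashlib.sha256()
        for p in self._params:
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    @contextmanager
    def frozen(self):
        """Temporarily exclude parameters from gradient accumulation.

        Gradients still flow *through* the network's activations (the
        adversarial term needs d(score)/d(segmap)); they are simply not
        accumulated into the frozen parameters.  Freezing is captured at
        graph-construction time, so backward() may run after the context
        exits.  Re-entrant.
        """
        prev = [p.requires_grad for p in self._params]
        for p in self._params:
            p.requires_grad = False
        try:
            yield self
        finally:
            for p, r in zip(self._params, prev):
                p.requires_grad = r


# ---------------------------------------------------------------------
# networks

class SegmentationNetwork(_Module):
    """Dense-block U-net mapping NCHW RGB to a 2-channel probability map."""

    def __init__(self, config: SegNetConfig = SegNetConfig(), seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(self.seed, 7001)))
        c = config.base_channels
        widths = [config.base_channels * 2 ** s
                  for s in range(config.n_scales + 1)]

        self.stem = _Conv(rng, 3, c, k=3, dtype=dtype)
        self.enc_blocks, self.enc_compress = [], []
        for s in range(config.n_scales):
            blk = _DenseBlock(rng, widths[s], config.dense_block_depth,
                              config.growth_rate, dtype=dtype)
            self.enc_blocks.append(blk)
            self.enc_compress.append(_Conv(rng, blk.c_out, widths[s + 1], k=1,
                                           dtype=dtype))
        bott_in = widths[config.n_scales]
        self.bottleneck = _DenseBlock(rng, bott_in, config.dense_block_depth,
                                      config.growth_rate, dtype=dtype)
        self.bott_compress = _Conv(rng, self.bottleneck.c_out, bott_in, k=1,
                                   dtype=dtype)

        self.dec_blocks, self.dec_compress = [], []
        for s in reversed(range(config.n_scales)):
            c_cat = widths[s + 1] + self.enc_blocks[s].c_out
            blk = _DenseBlock(rng, c_cat, config.dense_block_depth,
                              config.growth_rate, dtype=dtype)
            self.dec_blocks.append(blk)
            self.dec_compress.append(_Conv(rng, blk.c_out, widths[s], k=1,
                                           dtype=dtype))
        self.head = _Conv(rng, widths[0], 2, k=1, dtype=dtype)

        for layer in ([self.stem, *self.enc_blocks, *self.enc_compress,
                       self.bottleneck, self.bott_compress, *self.dec_blocks,
                       *self.dec_compress, self.head]):
            self._params.extend(layer.params)

    def _check_divisible(self, h, w):
        div = 2 ** self.config.n_scales
        if h % div or w % div:
            raise ValidationError(
                f"input {h}x{w} not divisible by 2^n_scales = {div}")

    def forward(self, x: Tensor) -> Tensor:
        """NCHW image batch -> NCHW 2-channel softmax probability batch."""
        n, c, h, w = x.shape
        self._check_divisible(h, w)
        y = ad.relu(self.stem(x))
        skips = []
        for blk, comp in zip(self.enc_blocks, self.enc_compress):
            feat = blk(y)
            skips.append(feat)
            y = ad.avg_pool2(ad.relu(comp(feat)))
        y = ad.relu(self.bott_compress(self.bottleneck(y)))
        for blk, comp, skip in zip(self.dec_blocks, self.dec_compress,
                                   reversed(skips)):
            y = ad.upsample2(y)
            y = ad.relu(comp(blk(ad.concat([y, skip], axis=1))))
        return ad.softmax_channels(self.head(y))

    __call__ = forward


class EvaluationNetwork(_Module):
    """Scores (image, segmentation map) pairs with one sigmoid scalar."""

    IN_CHANNELS = 5      # 3 image + 2 segmentation channels

    def __init__(self, config: EvalNetConfig = EvalNetConfig(), seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(self.seed, 7002)))
        self.convs = []
        c_in = self.IN_CHANNELS
        c = config.base_channels
        for i in range(config.n_downsamples):
            self.convs.append(_Conv(rng, c_in, c, k=3, stride=2, dtype=dtype))
            c_in = c
            c = min(c * 2, 4 * config.base_channels)
        wlin = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in, 1))
        self.w_out = Tensor(wlin.astype(dtype), requires_grad=True)
        self.b_out = Tensor(np.zeros(1, dtype=dtype), requires_grad=True)
        for conv in self.convs:
            self._params.extend(conv.params)
        self._params.extend([self.w_out, self.b_out])

    def forward(self, image: Tensor, segmap: Tensor) -> Tensor:
        """(N,3,H,W) image + (N,2,H,W) map -> (N,) scores in (0,1)."""
        if image.shape[0] != segmap.shape[0] or \
                image.shape[2:] != segmap.shape[2:]:
            raise ValidationError(
                f"image {image.shape} and segmap {segmap.shape} disagree")
        y = ad.concat([image, segmap], axis=1)
        for conv in self.convs:
            y = ad.relu(conv(y))
        y = ad.global_avg_pool(y)
        y = ad.linear(y, self.w_out, self.b_out)
        s = ad.sigmoid(y)
        return ad.mean(s, axis=1)        # (N,1) -> (N,)

    __call__ = forward


# ---------------------------------------------------------------------
# prediction container and numpy-facing wrappers

@dataclass
class PredictionMap:
    """Per-pixel class probabilities Ŷ: H×W×2, channels sum to 1."""

    probs: np.ndarray
    source_id: str = ""
    en_score: float | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != 2:
            raise ValidationError(
                f"PredictionMap must be HxWx2, got {self.probs.shape}")
        sums = self.probs.sum(axis=2)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValidationError("PredictionMap channels must sum to 1")

    @property
    def hard_mask(self) -> np.ndarray:
        """Argmax over channels: 1 where lesion probability dominates."""
        return (self.probs[:, :, 1] > self.probs[:, :, 0]).astype(np.uint8)


def _to_nchw(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 image, got {image.shape}")
    return image.transpose(2, 0, 1)[None]


def seg_forward(net: SegmentationNetwork, image: np.ndarray) -> PredictionMap:
    """Run the SN on one H×W×3 image (inference mode, deterministic)."""
    probs = net(Tensor(_to_nchw(image))).data[0].transpose(1, 2, 0)
    return PredictionMap(probs=probs)


def ev_forward(net: EvaluationNetwork, image: np.ndarray,
               segmap: np.ndarray) -> float:
    """Score one (H×W×3 image, H×W×2 map) pair; result lies in (0, 1)."""
    segmap = np.asarray(segmap, dtype=np.float64)
    if segmap.ndim != 3 or segmap.shape[2] != 2:
        raise ValidationError(f"expected HxWx2 segmap, got {segmap.shape}")
    if segmap.shape[:2] != image.shape[:2]:
        raise ValidationError(
            f"image {image.shape[:2]} and segmap {segmap.shape[:2]} disagree")
    score = net(Tensor(_to_nchw(image)),
                Tensor(segmap.transpose(2, 0, 1)[None]))
    return float(score.data[0])


def mask_to_map(mask: np.ndarray) -> np.ndarray:
    """Binary H×W mask -> one-hot H×W×2 map (channel 1 = lesion)."""
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValidationError("mask_to_map requires a binary mask")
    m = mask.astype(np.float64)
    return np.stack([1.0 - m, m], axis=2)


# ---------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, sn: SegmentationNetwork, en: EvaluationNetwork,
                    epoch: int = 0, seed: int = 0):
    """Write (θS, θE, configs, seed, epoch) to one portable .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "epoch": int(epoch),
        "seed": int(seed),
        "sn_config": asdict(sn.config),
        "en_config": asdict(en.config),
        "sn_seed": sn.seed,
        "en_seed": en.seed,
    }
    arrays = {f"sn_{i}": a for i, a in enumerate(sn.state_arrays())}
    arrays.update({f"en_{i}": a for i, a in enumerate(en.state_arrays())})
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Restore networks from :func:`save_checkpoint` output.

    Returns ``(sn, en, meta)`` with freshly constructed networks whose
    parameters are overwritten by the stored arrays.
    """
    with np.load(Path(path), allow_pickle=False) as zf:
        meta = json.loads(str(zf["meta"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(
                f"unsupported checkpoint version {meta.get('version')}")
        sn = SegmentationNetwork(SegNetConfig(**meta["sn_config"]),
                                 seed=meta["sn_seed"])
        en = EvaluationNetwork(EvalNetConfig(**meta["en_config"]),
                               seed=meta["en_seed"])
        sn.load_state_arrays([zf[f"sn_{i}"]
                              for i in range(len(sn.parameters))])
        en.load_state_arrays([zf[f"en_{i}"]
                              for i in range(len(en.parameters))])
    return sn, en, meta
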