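"""Composite objectives of the adversarial semi-supervised framework.

Three players and three objectives:

* the supervised segmentation loss ``L_seg = dice + bce`` between the
  SN's probability map and the one-hot ground truth of labeled images;
* the adversarial loss ``l_adv = λl·bce(Ev(x_l, Seg(x_l)), 1)
  + λu·bce(Ev(x_u, Seg(x_u)), 1)`` pushing the SN to produce maps the
  evaluation network scores as ground-truth-like, on labeled *and*
  unlabeled images — this is where unlabeled data enters training;
* the EN's discrimination loss ``l_E = bce(Ev(x_l, y_l), 1)
  + λl·bce(Ev(x_l, Seg(x_l)), 0) + λu·bce(Ev(x_u, Seg(x_u)), 0)``
  (real pairs labeled 1, predicted pairs 0).

The SN minimizes ``l_S = L_seg + λadv·l_adv`` with the EN's parameters
frozen; the EN minimizes ``l_E`` with the SN's predictions detached.
Every probability is clamped to [ε, 1−ε], ε = 1e-7, before any log.

All loss functions accept either plain numpy arrays (returning floats —
convenient for testing and evaluation) or autodiff Tensors in NCHW
layout (returning Tensors — used by the training loop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import NumericError, ValidationError
from .networks import EvaluationNetwork

__all__ = ["EPS", "LossWeights", "LossReport", "bce_loss", "dice_loss",
           "seg_supervised_loss", "adv_loss", "en_loss", "total_sn_loss"]

EPS = 1e-7
DICE_SMOOTH = 1.0


@dataclass(frozen=True)
class LossWeights:
    """λadv, λl, λu — all finite and non-negative.

    Defaults (0.01 / 1.0 / 0.5) keep the adversarial gradient small
    relative to the supervised term early in training while weighting
    labeled predictions more than unlabeled ones.
    """

    lambda_adv: float = 0.01
    lambda_l: float = 1.0
    lambda_u: float = 0.5

    def __post_init__(self):
        for name in ("lambda_adv", "lambda_l", "lambda_u"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class LossReport:
    """One training step's loss decomposition (a row of the training log)."""

    l_seg: float
    l_adv: float
    l_S: float
    l_E: float = 0.0
    components: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"l_seg": self.l_seg, "l_adv": self.l_adv,
               "l_S": self.l_S, "l_E": self.l_E}
        row.update(self.components)
        return row


# ---------------------------------------------------------------------
# helpers

def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _map_to_nchw(x) -> Tensor:
    """Accept H×W×2 numpy or (N,2,H,W) Tensor; return NCHW Tensor."""
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3 and x.shape[2] == 2:
        return Tensor(x.transpose(2, 0, 1)[None])
    if x.ndim == 4 and x.shape[1] == 2:
        return Tensor(x)
    raise ValidationError(f"expected HxWx2 map or NCHW batch, got {x.shape}")


def _batch_size(x) -> int:
    if x is None:
        return 0
    return x.shape[0] if isinstance(x, Tensor) else np.asarray(x).shape[0]


# ---------------------------------------------------------------------
# elementary losses

def _bce_t(pred: Tensor, target) -> Tensor:
    """Fused mean BCE node: clamp + log terms + mean in one op.

    `target` is a Tensor or array; no gradient is propagated to it.
    Fusing keeps the elementwise intermediates out of the graph, which
    matters because this runs on every pixel of every training batch.
    """
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    p = np.clip(pred.data, EPS, 1.0 - EPS)
    t = np.broadcast_to(t, p.shape)
    val = -(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean()
    pred_req = pred.requires_grad
    inside = (pred.data > EPS) & (pred.data < 1.0 - EPS)

    def bw(g):
        if pred_req:
            dp = -(t / p - (1.0 - t) / (1.0 - p)) / p.size
            pred._accumulate(g * dp * inside)

    return Tensor(val, parents=(pred,), backward=bw)


def bce_loss(pred, target):
    """Mean binary cross-entropy −[t·log p + (1−t)·log(1−p)].

    `pred` holds probabilities; `target` may be binary or soft, same
    shape (or a scalar, broadcast).  Probabilities are clamped at ε.
    """
    tensor_mode = _is_tensor(pred, target)
    p, t = _t(pred), _t(target)
    if p.shape != t.shape and t.data.size != 1:
        raise ValidationError(
            f"bce_loss shape mismatch: pred {p.shape}, target {t.shape}")
    out = _bce_t(p, t)
    return out if tensor_mode else out.item()


def _dice_t(pred: Tensor, target: Tensor, smooth: float = DICE_SMOOTH) -> Tensor:
    """Soft Dice loss over NCHW maps, averaged over samples and channels."""
    inter = ad.tensor_sum(pred * target, axis=(2, 3))           # (N, C)
    denom = ad.tensor_sum(pred, axis=(2, 3)) + ad.tensor_sum(target, axis=(2, 3))
    dice = ad.div(2.0 * inter + smooth, denom + smooth)
    return ad.mean(1.0 - dice)


def dice_loss(pred, target):
    """Soft Dice loss 1 − (2Σpt + s)/(Σp + Σt + s), s = 1, channel-mean."""
    tensor_mode = _is_tensor(pred, target)
    p, t = _map_to_nchw(pred), _map_to_nchw(target)
    if p.shape != t.shape:
        raise ValidationError(
            f"dice_loss shape mismatch: pred {p.shape}, target {t.shape}")
    out = _dice_t(p, t)
    return out if tensor_mode else out.item()


def seg_supervised_loss(pred, gt):
    """Supervised loss on labeled data: dice_loss + bce_loss (unit weights)."""
    tensor_mode = _is_tensor(pred, gt)
    p, t = _map_to_nchw(pred), _map_to_nchw(gt)
    if p.shape != t.shape:
        raise ValidationError(
            f"seg_supervised_loss shape mismatch: {p.shape} vs {t.shape}")
    out = _dice_t(p, t) + _bce_t(p, t)
    return out if tensor_mode else out.item()


# ---------------------------------------------------------------------
# adversarial objectives

def _score_bce(en, x, segmap, label: float) -> Tensor:
    scores = en(x, segmap)
    target = Tensor(np.full(scores.shape, label))
    return _bce_t(scores, target)


def adv_loss(en: EvaluationNetwork, x_l, x_u, pred_l, pred_u,
             weights: LossWeights):
    """Adversarial term of the SN objective (EN parameters frozen).

    λl·bce(Ev(x_l, Seg(x_l)), 1) + λu·bce(Ev(x_u, Seg(x_u)), 1).
    Gradients flow through the EN into the segmentation maps but never
    into θE.  An empty unlabeled batch zeroes the λu term.
    """
    n_l, n_u = _batch_size(x_l), _batch_size(x_u)
    if n_l == 0 and n_u == 0:
        raise ValidationError("adv_loss requires at least one non-empty batch")
    tensor_mode = _is_tensor(x_l, x_u, pred_l, pred_u)
    with en.frozen():
        total = Tensor(0.0)
        if n_l > 0 and weights.lambda_l > 0:
            total = total + weights.lambda_l * _score_bce(
                en, _t(x_l), _map_to_nchw(pred_l), 1.0)
        if n_u > 0 and weights.lambda_u > 0:
            total = total + weights.lambda_u * _score_bce(
                en, _t(x_u), _map_to_nchw(pred_u), 1.0)
    return total if tensor_mode else total.item()


def en_loss(en: EvaluationNetwork, x_l, y_l, x_u, pred_l, pred_u,
            weights: LossWeights):
    """Discrimination objective of the EN (SN predictions detached).

    bce(Ev(x_l, y_l), 1) + λl·bce(Ev(x_l, Seg(x_l)), 0)
                         + λu·bce(Ev(x_u, Seg(x_u)), 0).
    The real-pair term is mandatory, so the labeled batch must be
    non-empty.
    """
    if _batch_size(x_l) == 0:
        raise ValidationError("en_loss requires a non-empty labeled batch")
    tensor_mode = _is_tensor(x_l, y_l, x_u, pred_l, pred_u)
    x_l_t = _t(x_l)
    total = _score_bce(en, x_l_t, _map_to_nchw(y_l).detach(), 1.0)
    if weights.lambda_l > 0:
        total = total + weights.lambda_l * _score_bce(
            en, x_l_t, _map_to_nchw(pred_l).detach(), 0.0)
    if _batch_size(x_u) > 0 and weights.lambda_u > 0:
        total = total + weights.lambda_u * _score_bce(
            en, _t(x_u), _map_to_nchw(pred_u).detach(), 0.0)
    return total if tensor_mode else total.item()


def total_sn_loss(l_seg: float, l_adv: float, weights: LossWeights
                  ) -> LossReport:
    """Combine the SN terms: l_S = l_seg + λadv · l_adv."""
    for name, v in (("l_seg", l_seg), ("l_adv", l_adv)):
        if not math.isfinite(float(v)):
            raise NumericError(f"non-finite loss component {name} = {v}")
    l_seg, l_adv = float(l_seg), float(l_adv)
    l_s = l_seg + weights.lambda_adv * l_adv
    return LossReport(l_seg=l_seg, l_adv=l_adv, l_S=l_s,
                      components={"lambda_adv": weights.lambda_adv,
                                  "lambda_l": weights.lambda_l,
                                  "lambda_u": weights.lambda_u})
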