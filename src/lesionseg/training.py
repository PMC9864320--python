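"""Supervised pretraining, adversarial co-training, and the experiment driver.

Training happens in two phases.  *Pretraining* fits the segmentation
network (SN) alone on the labeled pool by minimizing dice+bce.
*Semi-supervised co-training* then alternates, once per step:

  (a) sample a labeled batch and an unlabeled batch;
  (b) update the evaluation network (EN) on its discrimination loss,
      with the SN's predictions detached;
  (c) update the SN on dice+bce plus λadv times the adversarial loss,
      with the EN's parameters frozen.

Optimizers follow the published recipe: SGD (lr 0.001, weight decay
1e-4) for the SN and Adam (lr 0.001) for the EN.  Runs are fully
deterministic given the config seed: batch order is drawn from
substreams keyed by (seed, stream, epoch), so a run with all loss
weights zero and no unlabeled pool reproduces a plain supervised run
bit for bit.

`run_protocol` reproduces the fixed-labeled / growing-unlabeled
experiment grid on synthetic phantoms: one cached pretraining, one
supervised-only continuation arm, and one SSL arm per unlabeled pool
size, each evaluated on a fixed test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import SGD, Adam, Tensor
from .dataio import DatasetSplit
from .errors import ValidationError
from .losses import LossWeights, _bce_t, _dice_t, adv_loss, en_loss, \
    total_sn_loss
from .metrics import evaluate
from .networks import EvalNetConfig, EvaluationNetwork, PredictionMap, \
    SegNetConfig, SegmentationNetwork, save_checkpoint
from .phantom import PhantomConfig, generate_split

__all__ = ["TrainConfig", "TrainState", "pretrain", "train_ssl", "predict",
           "run_protocol", "ProtocolReport"]

_LABELED_STREAM = 11
_UNLABELED_STREAM = 12


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Published-scale values (192×192 inputs, batch 16, 4000 epochs) are
    available through :meth:`paper_scale`; the defaults here are the
    desk-scale profile every test uses (64×64, batch 8, 30 pretraining
    + 60 co-training epochs), which trains in minutes on one CPU.
    """

    sn_lr: float = 0.001
    sn_weight_decay: float = 0.0001
    en_lr: float = 0.001
    batch_size: int = 8
    pretrain_epochs: int = 30
    ssl_epochs: int = 60
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    sn_config: SegNetConfig = field(default_factory=SegNetConfig)
    en_config: EvalNetConfig = field(default_factory=EvalNetConfig)
    val_every: int = 1          # epochs between validation-DSC passes; 0 = off
    checkpoint_every: int = 0   # epochs between checkpoints; 0 = off
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.sn_lr <= 0 or self.en_lr <= 0:
            raise ValidationError("learning rates must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.pretrain_epochs < 1 or self.ssl_epochs < 1:
            raise ValidationError("epoch counts must be >= 1")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale profile with the smallest workable networks.

        The SN learning rate is raised to 0.05: the published 0.001 is
        tuned for thousands of epochs on thousands of images, and at
        tens of epochs on tens of phantoms plain SGD at 0.001 never
        escapes the all-background solution.
        """
        kw = dict(sn_config=SegNetConfig.tiny(), en_config=EvalNetConfig.tiny(),
                  sn_lr=0.05, seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def paper_scale(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Published-scale profile: batch 16, 4000 co-training epochs."""
        kw = dict(batch_size=16, pretrain_epochs=400, ssl_epochs=4000,
                  seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainState:
    sn: SegmentationNetwork
    en: EvaluationNetwork
    epoch: int = 0
    history: list = field(default_factory=list)    # one dict per epoch
    step_log: list = field(default_factory=list)   # one LossReport per step

    def write_step_log(self, path):
        """Dump the per-step loss decomposition as JSONL."""
        with open(Path(path), "w") as fh:
            for i, rep in enumerate(self.step_log):
                fh.write(json.dumps({"step": i, **rep.to_row()}) + "\n")


# ---------------------------------------------------------------------
# data plumbing

def _stack_images(samples) -> np.ndarray:
    # float32: matches the networks' parameter dtype, halves memory traffic
    return np.stack([s.image.transpose(2, 0, 1)
                     for s in samples]).astype(np.float32)


def _stack_masks(samples) -> np.ndarray:
    m = np.stack([s.mask for s in samples]).astype(np.float32)
    return np.stack([1.0 - m, m], axis=1)                   # N,2,H,W


def _epoch_rng(seed: int, stream: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), stream, int(epoch))))


def _labeled_batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _clone_networks(state: TrainState, config: TrainConfig):
    sn = SegmentationNetwork(state.sn.config, seed=state.sn.seed)
    sn.load_state_arrays(state.sn.state_arrays())
    en = EvaluationNetwork(state.en.config, seed=state.en.seed)
    en.load_state_arrays(state.en.state_arrays())
    return sn, en


def _validation_dsc(sn: SegmentationNetwork, test_samples) -> float:
    if not test_samples:
        return float("nan")
    maps = _predict_batched(sn, test_samples)
    report = evaluate(maps, [s.mask for s in test_samples],
                      [s.source_id for s in test_samples])
    return report.aggregate["dsc"][0]


def _predict_batched(sn: SegmentationNetwork, samples, batch_size: int = 16):
    maps = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        probs = sn(Tensor(_stack_images(chunk))).data
        for s, p in zip(chunk, probs):
            maps.append(PredictionMap(probs=p.transpose(1, 2, 0),
                                      source_id=s.source_id))
    return maps


def _maybe_checkpoint(state: TrainState, config: TrainConfig, phase: str):
    if config.checkpoint_every and config.checkpoint_dir and \
            state.epoch % config.checkpoint_every == 0:
        save_checkpoint(Path(config.checkpoint_dir) /
                        f"{phase}_epoch{state.epoch:05d}.npz",
                        state.sn, state.en, epoch=state.epoch,
                        seed=config.seed)


# ---------------------------------------------------------------------
# phase 1: supervised pretraining

def pretrain(split: DatasetSplit, config: TrainConfig,
             init: TrainState | None = None) -> TrainState:
    """Train the SN on the labeled pool only; the EN is left untouched.

    Pass ``init`` to continue from an earlier state (networks are
    cloned, the input state is never mutated).
    """
    if not split.labeled:
        raise ValidationError("pretrain requires a non-empty labeled pool")
    if init is None:
        sn = SegmentationNetwork(config.sn_config, seed=config.seed)
        en = EvaluationNetwork(config.en_config, seed=config.seed)
    else:
        sn, en = _clone_networks(init, config)
    state = TrainState(sn=sn, en=en)
    opt = SGD(sn.parameters, lr=config.sn_lr,
              weight_decay=config.sn_weight_decay)

    x_all = _stack_images(split.labeled)
    y_all = _stack_masks(split.labeled)
    for epoch in range(config.pretrain_epochs):
        rng = _epoch_rng(config.seed, _LABELED_STREAM, epoch)
        losses = []
        for idx in _labeled_batches(len(split.labeled), config.batch_size,
                                    rng):
            pred = sn(Tensor(x_all[idx]))
            y = Tensor(y_all[idx])
            loss = _dice_t(pred, y) + _bce_t(pred, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            l_seg = loss.item()
            losses.append(l_seg)
            state.step_log.append(
                total_sn_loss(l_seg, 0.0, config.loss_weights))
        state.epoch = epoch + 1
        val = _validation_dsc(sn, split.test) \
            if config.val_every and (epoch + 1) % config.val_every == 0 \
            else float("nan")
        state.history.append({"epoch": state.epoch,
                              "l_seg": float(np.mean(losses)),
                              "l_adv": 0.0,
                              "l_S": float(np.mean(losses)),
                              "l_E": float("nan"), "val_dsc": val})
        _maybe_checkpoint(state, config, "pretrain")
    return state


# ---------------------------------------------------------------------
# phase 2: adversarial semi-supervised co-training

def train_ssl(split: DatasetSplit, pretrained: TrainState,
              config: TrainConfig, on_step=None) -> TrainState:
    """Adversarial co-training of SN and EN on labeled + unlabeled data.

    Requires the pretrained state from :func:`pretrain` (the published
    pipeline never starts adversarial training from scratch).  The
    unlabeled pool may be empty, in which case the λu terms vanish; with
    all loss weights zero the SN trajectory reduces exactly to continued
    supervised training.

    ``on_step(step_index, stage, state)`` — optional instrumentation
    callback invoked at stages ``"step_start"``, ``"en_updated"`` and
    ``"sn_updated"`` of every alternation.
    """
    if pretrained is None:
        raise ValidationError(
            "train_ssl requires the pretrained state from pretrain()")
    if not split.labeled:
        raise ValidationError("train_ssl requires a non-empty labeled pool")
    sn, en = _clone_networks(pretrained, config)
    state = TrainState(sn=sn, en=en)
    w = config.loss_weights
    sn_opt = SGD(sn.parameters, lr=config.sn_lr,
                 weight_decay=config.sn_weight_decay)
    en_opt = Adam(en.parameters, lr=config.en_lr)

    x_lab = _stack_images(split.labeled)
    y_lab = _stack_masks(split.labeled)
    x_unl = _stack_images(split.unlabeled) if split.unlabeled else None
    n_unl = 0 if x_unl is None else len(x_unl)
    use_unlabeled = n_unl > 0 and w.lambda_u > 0

    for epoch in range(config.ssl_epochs):
        rng_l = _epoch_rng(config.seed, _LABELED_STREAM, epoch)
        rng_u = _epoch_rng(config.seed, _UNLABELED_STREAM, epoch)
        sums = {"l_seg": 0.0, "l_adv": 0.0, "l_S": 0.0, "l_E": 0.0}
        batches = _labeled_batches(len(split.labeled), config.batch_size,
                                   rng_l)
        for idx in batches:
            if on_step is not None:
                on_step(len(state.step_log), "step_start", state)
            x_l, y_l = Tensor(x_lab[idx]), Tensor(y_lab[idx])
            if use_unlabeled:
                # with replacement: the pool is usually far larger than
                # the labeled pool that sets the step count
                u_idx = rng_u.integers(0, n_unl, size=config.batch_size)
                x_u = Tensor(x_unl[u_idx])
            else:
                x_u = None

            pred_l = sn(x_l)
            pred_u = sn(x_u) if x_u is not None else None

            # (b) EN step: discriminate real from predicted pairs
            l_e_t = en_loss(en, x_l, y_l, x_u, pred_l, pred_u, w)
            en_opt.zero_grad()
            l_e_t.backward()
            en_opt.step()
            if on_step is not None:
                on_step(len(state.step_log), "en_updated", state)

            # (c) SN step: supervised + adversarial, EN frozen
            l_seg_t = _dice_t(pred_l, y_l) + _bce_t(pred_l, y_l)
            if w.lambda_adv > 0:
                l_adv_t = adv_loss(en, x_l, x_u, pred_l, pred_u, w)
                l_total = l_seg_t + w.lambda_adv * l_adv_t
                l_adv_val = l_adv_t.item()
            else:
                l_total = l_seg_t
                l_adv_val = 0.0
            sn_opt.zero_grad()
            l_total.backward()
            sn_opt.step()
            if on_step is not None:
                on_step(len(state.step_log), "sn_updated", state)

            rep = total_sn_loss(l_seg_t.item(), l_adv_val, w)
            rep.l_E = l_e_t.item()
            state.step_log.append(rep)
            for k in sums:
                sums[k] += getattr(rep, k)

        state.epoch = epoch + 1
        ns = len(batches)
        val = _validation_dsc(sn, split.test) \
            if config.val_every and (epoch + 1) % config.val_every == 0 \
            else float("nan")
        state.history.append({"epoch": state.epoch,
                              **{k: v / ns for k, v in sums.items()},
                              "val_dsc": val})
        _maybe_checkpoint(state, config, "ssl")
    return state


# ---------------------------------------------------------------------
# inference

def predict(state: TrainState, samples: list,
            attach_en_score: bool = False) -> list:
    """SN inference on a list of samples; deterministic.

    With ``attach_en_score=True`` each map also carries the EN's quality
    score for the (image, predicted map) pair.
    """
    for s in samples:
        div = 2 ** state.sn.config.n_scales
        if s.height % div or s.width % div:
            raise ValidationError(
                f"sample '{s.source_id}' is {s.height}x{s.width}; "
                f"dimensions must be divisible by {div}")
    maps = _predict_batched(state.sn, samples)
    if attach_en_score:
        for s, m in zip(samples, maps):
            score = state.en(Tensor(_stack_images([s])),
                             Tensor(m.probs.transpose(2, 0, 1)[None]))
            m.en_score = float(score.data[0])
    return maps


# ---------------------------------------------------------------------
# protocol driver

@dataclass
class ProtocolReport:
    """Grid of metric aggregates: one supervised row + one row per pool size."""

    labeled_n: int
    rows: list = field(default_factory=list)   # (label, n_unlabeled, aggregate)
    reports: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        data = []
        for label, n_u, agg in self.rows:
            row = {"split": label, "n_unlabeled": n_u}
            for metric, (m, s) in agg.items():
                row[metric] = f"{m:.2f} ± {s:.2f}"
            data.append(row)
        return pd.DataFrame(data)

    def dsc(self, label: str) -> float:
        for lab, _, agg in self.rows:
            if lab == label:
                return agg["dsc"][0]
        raise KeyError(label)

    def __str__(self):
        return self.to_dataframe().to_string(index=False)


def run_protocol(labeled_n: int, unlabeled_ns: list, phantom: PhantomConfig,
                 config: TrainConfig) -> ProtocolReport:
    """Fixed labeled pool, growing unlabeled pool, shared test set.

    Generates one phantom world, pretrains once, then trains (i) a
    supervised-only continuation arm (all loss weights zero, no
    unlabeled data) and (ii) one SSL arm per entry of ``unlabeled_ns``
    using the first n samples of the same unlabeled pool.  Every arm is
    scored on the same held-out test set.
    """
    if any(n < 0 for n in unlabeled_ns):
        raise ValidationError("unlabeled pool sizes must be >= 0")
    phantom = replace(phantom, n_labeled=labeled_n)
    split = generate_split(phantom)
    for n_u in unlabeled_ns:
        if n_u > len(split.unlabeled):
            raise ValidationError(
                f"requested {n_u} unlabeled samples, pool has "
                f"{len(split.unlabeled)}")

    pre = pretrain(split, config)
    report = ProtocolReport(labeled_n=labeled_n)

    def arm(label, n_u, arm_split, arm_config):
        state = train_ssl(arm_split, pre, arm_config)
        maps = predict(state, arm_split.test)
        rep = evaluate(maps, [s.mask for s in arm_split.test],
                       [s.source_id for s in arm_split.test])
        report.rows.append((label, n_u, rep.aggregate))
        report.reports[label] = rep

    sup_split = DatasetSplit(labeled=split.labeled, unlabeled=[],
                             test=split.test)
    sup_config = replace(config, loss_weights=LossWeights(0.0, 0.0, 0.0))
    arm(f"{labeled_n}/0 (supervised)", 0, sup_split, sup_config)

    for n_u in unlabeled_ns:
        arm_split = DatasetSplit(labeled=split.labeled,
                                 unlabeled=split.unlabeled[:n_u],
                                 test=split.test)
        arm(f"{labeled_n}/{n_u}", n_u, arm_split, config)
    return report
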