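"""Closed-form identities and gradient-flow contracts of the objectives."""

import math

import numpy as np
import pytest

import lesionseg as ls
from lesionseg import autodiff as ad
from lesionseg.autodiff import Tensor
from lesionseg.errors import NumericError, ValidationError
from lesionseg.losses import EPS, _bce_t
from lesionseg.networks import EvalNetConfig, SegNetConfig

LN2 = math.log(2.0)


class _StubEN:
    """Evaluation-network stand-in emitting a constant score (synthetic)."""

    def __init__(self, score=0.5):
        self.score = score
        self.parameters = []

    def __call__(self, image, segmap):
        n = image.shape[0]
        return Tensor(np.full(n, self.score))

    def frozen(self):
        import contextlib
        return contextlib.nullcontext(self)


class TestBce:
    def test_uniform_half_prediction_is_ln2(self, rng):
        pred = np.full((16, 16), 0.5)
        target = rng.integers(0, 2, size=(16, 16)).astype(float)
        assert ls.bce_loss(pred, target) == pytest.approx(LN2, abs=1e-9)

    def test_single_element_closed_form(self):
        assert ls.bce_loss(np.array([0.25]), np.array([1.0])) == \
            pytest.approx(-math.log(0.25), abs=1e-9)

    def test_perfect_prediction_is_near_zero(self):
        pred = np.ones((8, 8))
        assert ls.bce_loss(pred, np.ones((8, 8))) < 1e-5

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(ls.bce_loss(np.zeros((4, 4)), np.ones((4, 4))))
        assert ls.bce_loss(np.zeros((4, 4)), np.ones((4, 4))) == \
            pytest.approx(-math.log(EPS), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ls.bce_loss(np.ones((3, 3)), np.ones((2, 2)))

    def test_gradient_matches_finite_difference(self, rng):
        p = rng.uniform(0.1, 0.9, size=(5, 5))
        t = rng.integers(0, 2, size=(5, 5)).astype(float)
        pt = Tensor(p, requires_grad=True)
        _bce_t(pt, t).backward()
        eps = 1e-7
        idx = (2, 3)
        p1, p2 = p.copy(), p.copy()
        p1[idx] += eps
        p2[idx] -= eps
        num = (ls.bce_loss(p1, t) - ls.bce_loss(p2, t)) / (2 * eps)
        assert pt.grad[idx] == pytest.approx(num, rel=1e-5)


class TestDice:
    def test_perfect_overlap_near_zero(self, checkerboard_mask):
        m = ls.mask_to_map(checkerboard_mask)
        assert ls.dice_loss(m, m) < 1e-2      # only smoothing keeps it > 0

    def test_total_miss_closed_form(self):
        # prediction puts zero mass on the foreground channel everywhere
        # while the target is all-foreground on N pixels: that channel
        # contributes 1 - s/(N + s); the background channel the mirror term
        n = 8 * 8
        target = ls.mask_to_map(np.ones((8, 8), dtype=np.uint8))
        pred = ls.mask_to_map(np.zeros((8, 8), dtype=np.uint8))
        expected = 0.5 * ((1 - 1 / (n + 1)) + (1 - 1 / (n + 1)))
        assert ls.dice_loss(pred, target) == pytest.approx(expected, abs=1e-9)

    def test_channel_swap_symmetry(self, rng):
        p = rng.uniform(size=(6, 6, 2))
        p /= p.sum(axis=2, keepdims=True)
        t = ls.mask_to_map(rng.integers(0, 2, size=(6, 6)).astype(np.uint8))
        assert ls.dice_loss(p, t) == pytest.approx(
            ls.dice_loss(p[:, :, ::-1], t[:, :, ::-1]), abs=1e-12)

    def test_range(self, rng):
        for _ in range(5):
            p = rng.uniform(size=(5, 5, 2))
            p /= p.sum(axis=2, keepdims=True)
            t = ls.mask_to_map(rng.integers(0, 2, (5, 5)).astype(np.uint8))
            assert 0.0 <= ls.dice_loss(p, t) < 1.0


class TestSupervisedLoss:
    def test_equals_sum_of_parts(self, rng):
        p = rng.uniform(size=(8, 8, 2))
        p /= p.sum(axis=2, keepdims=True)
        t = ls.mask_to_map(rng.integers(0, 2, (8, 8)).astype(np.uint8))
        assert ls.seg_supervised_loss(p, t) == pytest.approx(
            ls.dice_loss(p, t) + ls.bce_loss(p, t), abs=1e-12)

    def test_perfect_prediction_small(self, checkerboard_mask):
        m = ls.mask_to_map(checkerboard_mask)
        assert ls.seg_supervised_loss(m, m) < 1e-2

    def test_decreases_toward_ground_truth(self, rng):
        t = ls.mask_to_map(rng.integers(0, 2, (8, 8)).astype(np.uint8))
        p = rng.uniform(size=(8, 8, 2))
        p /= p.sum(axis=2, keepdims=True)
        closer = p + 0.1 * (t - p)
        assert ls.seg_supervised_loss(closer, t) < ls.seg_supervised_loss(p, t)


class TestAdversarialLosses:
    def _batches(self, rng, n_l=3, n_u=2, hw=16):
        x_l = rng.uniform(size=(n_l, 3, hw, hw)).astype(np.float32)
        x_u = rng.uniform(size=(n_u, 3, hw, hw)).astype(np.float32)
        pred = rng.uniform(size=(n_l, 2, hw, hw))
        pred /= pred.sum(axis=1, keepdims=True)
        pred_u = rng.uniform(size=(n_u, 2, hw, hw))
        pred_u /= pred_u.sum(axis=1, keepdims=True)
        y_l = np.stack([ls.mask_to_map(rng.integers(0, 2, (hw, hw))
                                       .astype(np.uint8)).transpose(2, 0, 1)
                        for _ in range(n_l)])
        return x_l, y_l, x_u, pred, pred_u

    def test_adv_stub_closed_form(self, rng):
        # a constant-0.5 discriminator scores every pair at bce = ln 2
        x_l, _, x_u, p_l, p_u = self._batches(rng)
        w = ls.LossWeights(lambda_adv=0.01, lambda_l=1.0, lambda_u=0.5)
        val = ls.adv_loss(_StubEN(), x_l, x_u, p_l, p_u, w)
        assert val == pytest.approx((w.lambda_l + w.lambda_u) * LN2, abs=1e-9)

    def test_en_stub_closed_form(self, rng):
        x_l, y_l, x_u, p_l, p_u = self._batches(rng)
        w = ls.LossWeights(lambda_adv=0.01, lambda_l=1.0, lambda_u=0.5)
        val = ls.en_loss(_StubEN(), x_l, y_l, x_u, p_l, p_u, w)
        assert val == pytest.approx((1 + w.lambda_l + w.lambda_u) * LN2,
                                    abs=1e-9)

    def test_lambda_u_zero_ignores_unlabeled(self, rng):
        x_l, y_l, x_u, p_l, p_u = self._batches(rng)
        w0 = ls.LossWeights(lambda_adv=0.01, lambda_l=1.0, lambda_u=0.0)
        a = ls.adv_loss(_StubEN(), x_l, x_u, p_l, p_u, w0)
        b = ls.adv_loss(_StubEN(), x_l, None, p_l, None, w0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_fooled_discriminator_limit(self, rng):
        x_l, _, x_u, p_l, p_u = self._batches(rng)
        w = ls.LossWeights()
        val = ls.adv_loss(_StubEN(score=1.0 - 1e-9), x_l, x_u, p_l, p_u, w)
        assert val < 1e-5

    def test_perfect_discriminator_en_loss_small(self, rng):
        x_l, y_l, x_u, p_l, p_u = self._batches(rng)

        class _Perfect(_StubEN):
            def __call__(self, image, segmap):
                # scores 1 on one-hot maps, 0 on soft ones
                onehot = bool(np.isin(segmap.data, (0.0, 1.0)).all())
                return Tensor(np.full(image.shape[0],
                                      1.0 - 1e-9 if onehot else 1e-9))

        val = ls.en_loss(_Perfect(), x_l, y_l, x_u, p_l, p_u,
                         ls.LossWeights())
        assert val < 1e-5

    def test_empty_batches_rejected(self, rng):
        _, y_l, _, p_l, _ = self._batches(rng)
        with pytest.raises(ValidationError):
            ls.adv_loss(_StubEN(), None, None, None, None, ls.LossWeights())
        with pytest.raises(ValidationError):
            ls.en_loss(_StubEN(), None, y_l, None, p_l, None,
                       ls.LossWeights())

    def test_gradient_isolation_by_finite_differences(self, rng):
        # the adversarial term must have zero gradient wrt theta_E and the
        # EN term zero gradient wrt theta_S (via detached predictions)
        en = ls.EvaluationNetwork(EvalNetConfig(base_channels=2,
                                                n_downsamples=2),
                                  seed=0, dtype=np.float64)
        sn = ls.SegmentationNetwork(SegNetConfig(base_channels=2,
                                                 dense_block_depth=1,
                                                 growth_rate=2, n_scales=1),
                                    seed=0, dtype=np.float64)
        hw = 8
        x_l = Tensor(rng.uniform(size=(2, 3, hw, hw)))
        x_u = Tensor(rng.uniform(size=(2, 3, hw, hw)))
        y_l = Tensor(np.stack([ls.mask_to_map(
            rng.integers(0, 2, (hw, hw)).astype(np.uint8)).transpose(2, 0, 1)
            for _ in range(2)]))
        w = ls.LossWeights(lambda_adv=1.0, lambda_l=1.0, lambda_u=0.5)

        # adv_loss graph writes no grad into theta_E even though the
        # score depends on theta_E (frozen-at-construction semantics),
        # while the SN still receives gradient through the EN's input
        out = ls.adv_loss(en, x_l, x_u, sn(x_l), sn(x_u), w)
        out.backward()
        assert all(p.grad is None for p in en.parameters)
        assert any(p.grad is not None for p in sn.parameters)

        # en_loss treats the SN predictions as constants: with the
        # detached maps held fixed, finite differences in theta_S leave
        # the loss bit-identical, and backward writes no SN grads
        pred_l = sn(x_l).detach()
        pred_u = sn(x_u).detach()
        p_s = sn.parameters[0]
        b1 = ls.en_loss(en, x_l, y_l, x_u, pred_l, pred_u, w).item()
        p_s.data[0, 0, 0, 0] += 1e-4
        b2 = ls.en_loss(en, x_l, y_l, x_u, pred_l, pred_u, w).item()
        p_s.data[0, 0, 0, 0] -= 1e-4
        assert b1 == b2
        for p in sn.parameters + en.parameters:
            p.grad = None
        out = ls.en_loss(en, x_l, y_l, x_u, sn(x_l), sn(x_u), w)
        out.backward()
        assert all(p.grad is None for p in sn.parameters)
        assert any(p.grad is not None for p in en.parameters)


class TestTotalLossAndWeights:
    def test_arithmetic_example(self):
        rep = ls.total_sn_loss(0.5, 0.2, ls.LossWeights(lambda_adv=0.01))
        assert rep.l_S == pytest.approx(0.502, abs=1e-12)

    def test_lambda_zero_supervised_limit(self):
        rep = ls.total_sn_loss(0.7, 5.0, ls.LossWeights(lambda_adv=0.0))
        assert rep.l_S == rep.l_seg == 0.7

    def test_report_invariant(self, rng):
        for _ in range(10):
            ls_, la = rng.uniform(0, 3, size=2)
            w = ls.LossWeights(lambda_adv=float(rng.uniform(0, 1)))
            rep = ls.total_sn_loss(ls_, la, w)
            assert rep.l_S == pytest.approx(rep.l_seg + w.lambda_adv * rep.l_adv,
                                            abs=1e-6)

    def test_nan_rejected_with_component_name(self):
        with pytest.raises(NumericError, match="l_adv"):
            ls.total_sn_loss(0.5, float("nan"), ls.LossWeights())

    def test_negative_weights_rejected(self):
        with pytest.raises(ValidationError):
            ls.LossWeights(lambda_adv=-0.1)
        with pytest.raises(ValidationError):
            ls.LossWeights(lambda_u=float("inf"))
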