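"""Dice loss, annotator-consistency loss, trace regularizer, parametric loss."""

import numpy as np
import pytest

from mammodense.errors import AnnotatorCountMismatch, ShapeMismatch
from mammodense.losses import (LossWeights, annotator_loss, dice_loss,
                               parametric_loss, soft_reconstruct_t, total_loss,
                               trace_term)
from mammodense.nn import Tensor


def _uniform_cm(value_matrix, shape=(1, 4, 4)):
    """Constant per-pixel 2x2 field from one matrix (B, H, W) spatial."""
    B, H, W = shape
    m = np.asarray(value_matrix, float)
    return np.broadcast_to(m[None, :, :, None, None], (B, 2, 2, H, W)).copy()


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self, rng):
        t = (rng.random((6, 6)) > 0.5).astype(float)
        assert dice_loss(t, t).item() < 1e-6

    def test_disjoint_near_one(self):
        t = np.zeros((4, 4)); t[:2] = 1
        assert dice_loss(1 - t, t).item() > 0.999

    def test_half_ones_uniform_half(self):
        # 1 - (2 * 1)/(2 + 2) = 0.5 on 4 pixels
        pred = np.full((2, 2), 0.5)
        target = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert dice_loss(pred, target).item() == pytest.approx(0.5, abs=1e-5)

    def test_bounded_and_flip_symmetric(self, rng):
        for _ in range(10):
            p = rng.random((5, 5))
            t = (rng.random((5, 5)) > 0.5).astype(float)
            v = dice_loss(p, t).item()
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(dice_loss(p[::-1], t[::-1]).item(), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatch):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def _identity_field(B=1, H=4, W=4):
    return _uniform_cm(np.eye(2), (B, H, W))


class TestAnnotatorLoss:
    def test_identity_field_reduces_to_dice(self, rng):
        probs = rng.random((1, 4, 4))
        y = np.stack([1 - probs, probs], axis=1)
        lab = (rng.random((1, 4, 4)) > 0.5).astype(float)
        a = annotator_loss(y, [_identity_field()], [lab]).item()
        b = dice_loss(probs, lab).item()
        assert a == pytest.approx(b, abs=1e-6)

    def test_two_identical_annotators_double(self, rng):
        probs = rng.random((1, 4, 4))
        y = np.stack([1 - probs, probs], axis=1)
        lab = (rng.random((1, 4, 4)) > 0.5).astype(float)
        one = annotator_loss(y, [_identity_field()], [lab]).item()
        two = annotator_loss(y, [_identity_field(), _identity_field()],
                             [lab, lab]).item()
        assert two == pytest.approx(2 * one, abs=1e-6)

    def test_matches_flat_loop_oracle(self, rng):
        B, H, W = 2, 3, 3
        probs = rng.random((B, H, W))
        y = np.stack([1 - probs, probs], axis=1)
        cms, labs = [], []
        for _ in range(2):
            raw = rng.random((B, 2, 2, H, W))
            cms.append(raw / raw.sum(axis=1, keepdims=True))
            labs.append((rng.random((B, H, W)) > 0.5).astype(float))
        got = annotator_loss(y, cms, labs).item()
        # oracle: explicit per-annotator dense-channel dice on scalars
        exp = 0.0
        for cm, lab in zip(cms, labs):
            num = den_p = den_t = 0.0
            for b in range(B):
                for r in range(H):
                    for c in range(W):
                        p_dense = (cm[b, 1, 0, r, c] * y[b, 0, r, c] +
                                   cm[b, 1, 1, r, c] * y[b, 1, r, c])
                        num += p_dense * lab[b, r, c]
                        den_p += p_dense
                        den_t += lab[b, r, c]
            exp += 1 - (2 * num + 1e-6) / (den_p + den_t + 1e-6)
        assert got == pytest.approx(exp, rel=1e-5)

    def test_count_mismatch(self):
        with pytest.raises(AnnotatorCountMismatch):
            annotator_loss(np.zeros((1, 2, 2, 2)), [_identity_field()], [])


class TestTraceTerm:
    def test_identity_fields(self):
        assert trace_term([_identity_field(), _identity_field()]).item() == \
            pytest.approx(4.0, abs=1e-6)

    def test_maximal_confusion(self):
        half = _uniform_cm([[0.5, 0.5], [0.5, 0.5]])
        assert trace_term([half]).item() == pytest.approx(1.0, abs=1e-6)

    def test_random_field_matches_loop_and_bounds(self, rng):
        raw = rng.random((2, 2, 2, 3, 3))
        cm = raw / raw.sum(axis=1, keepdims=True)
        got = trace_term([cm, cm]).item()
        exp = 0.0
        for _ in range(2):
            acc = 0.0
            for b in range(2):
                for r in range(3):
                    for c in range(3):
                        acc += cm[b, 0, 0, r, c] + cm[b, 1, 1, r, c]
            exp += acc / (2 * 3 * 3)
        assert got == pytest.approx(exp, rel=1e-5)
        assert 0.0 <= got <= 2 * 2

    def test_sum_reduction_scales_with_pixels(self):
        f = _identity_field(B=1, H=4, W=4)
        assert trace_term([f], reduction="sum").item() == pytest.approx(32.0, abs=1e-4)


class TestParametricLoss:
    def test_self_consistent_params_near_zero(self):
        img = np.array([[[0.2, 0.8], [0.9, 0.1]]])
        breast = np.ones((1, 2, 2))
        params = Tensor(np.array([[1.0, 0.5]]))
        soft = soft_reconstruct_t(img, params, breast, steepness=1e3).data
        y = np.stack([1 - soft, soft], axis=1)
        loss = parametric_loss(y, img, params, breast, steepness=1e3)
        assert loss.item() < 1e-3

    def test_empty_reconstruction_vs_confident_map(self):
        img = np.full((1, 4, 4), 0.5)
        breast = np.ones((1, 4, 4))
        params = Tensor(np.array([[1.0, 1.0]]))   # th_f = 1: empty soft mask
        y = np.stack([np.zeros((1, 4, 4)), np.ones((1, 4, 4))], axis=1)
        loss = parametric_loss(y, img, params, breast, steepness=1e3)
        assert loss.item() > 0.99

    def test_gradient_reaches_params_only_through_soft_mask(self, float64_engine, rng):
        img = rng.random((1, 4, 4))
        breast = np.ones((1, 4, 4))
        z = Tensor(np.array([[1.2, 0.4]]), requires_grad=True)
        probs = rng.random((1, 4, 4))
        y = np.stack([1 - probs, probs], axis=1)
        loss = parametric_loss(y, img, z, breast, steepness=10.0)
        loss.backward()
        g = z.grad.copy()
        for j in range(2):
            eps = 1e-6
            zp = z.data.copy(); zp[0, j] += eps
            zm = z.data.copy(); zm[0, j] -= eps
            lp = parametric_loss(y, img, Tensor(zp), breast, 10.0).item()
            lm = parametric_loss(y, img, Tensor(zm), breast, 10.0).item()
            assert g[0, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)


class TestTotalLoss:
    def test_weighted_combination(self):
        v = total_loss(0.5, 2.0, 0.1, LossWeights(0.9, 0.1)).item()
        assert v == pytest.approx(2.31, abs=1e-5)

    def test_zero_weights_reduce_to_theta(self):
        v = total_loss(0.7, 5.0, 9.0, LossWeights(0.0, 0.0)).item()
        assert v == pytest.approx(0.7, abs=1e-7)

    def test_default_weights(self):
        w = LossWeights()
        assert (w.alpha_loss, w.beta_loss) == (0.9, 0.1)

    def test_missing_terms_omitted(self):
        assert total_loss(l_theta=0.3).item() == pytest.approx(0.3, abs=1e-7)
        assert total_loss(l_phi=2.0, weights=LossWeights(0.5, 0.1)).item() == \
            pytest.approx(1.0, abs=1e-6)
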