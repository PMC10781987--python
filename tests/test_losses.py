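"""Inpainting and segmentation loss functions: hand-derived values and
elementwise oracles."""

import numpy as np
import pytest

from glomopaint import losses as L
from glomopaint.nd import Tensor


def _img(rng, n=1, c=3, h=8, w=8):
    return rng.random((n, c, h, w)).astype(np.float32)


def _mask_checker(n=1, h=2, w=2):
    m = np.indices((h, w)).sum(axis=0) % 2 == 0
    return np.broadcast_to(m, (n, 1, h, w)).astype(np.float32)


class TestInpaintInput:
    def test_zero_mask_keeps_image(self, rng):
        x = _img(rng)
        gap, inp = L.make_inpaint_input(x, np.zeros((1, 1, 8, 8), np.float32))
        assert np.array_equal(gap.data, x)
        assert inp.shape == (1, 4, 8, 8)

    def test_full_mask_blanks_image(self, rng):
        x = _img(rng)
        gap, _ = L.make_inpaint_input(x, np.ones((1, 1, 8, 8), np.float32))
        assert np.all(gap.data == 0)

    def test_elementwise_value(self):
        x = np.full((1, 1, 2, 2), 0.5, np.float32)
        mask = np.array([[[[1, 0], [0, 1]]]], np.float32)
        gap, inp = L.make_inpaint_input(x, mask)
        assert np.allclose(gap.data[0, 0], [[0, 0.5], [0.5, 0]])
        assert np.allclose(inp.data[0, 1], mask[0, 0])

    def test_elementwise_matches_loop_oracle(self, rng):
        x = _img(rng, c=3)
        mask = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        gap, _ = L.make_inpaint_input(x, mask)
        for c in range(3):
            for i in range(8):
                for j in range(8):
                    assert gap.data[0, c, i, j] == pytest.approx(
                        x[0, c, i, j] * (1 - mask[0, 0, i, j])
                    )

    def test_nonbinary_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            L.make_inpaint_input(_img(rng), np.full((1, 1, 8, 8), 0.5, np.float32))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            L.make_inpaint_input(_img(rng), np.zeros((1, 1, 4, 4), np.float32))


class TestLocalRegion:
    def test_zero_mask_gives_white(self, rng):
        r = L.local_region(_img(rng), np.zeros((1, 1, 8, 8), np.float32))
        assert np.all(r.data == 1.0)

    def test_full_mask_identity(self, rng):
        x = _img(rng)
        r = L.local_region(x, np.ones((1, 1, 8, 8), np.float32))
        assert np.allclose(r.data, x)

    def test_elementwise_value(self):
        x = np.full((1, 1, 2, 2), 0.25, np.float32)
        mask = np.array([[[[1, 0], [0, 0]]]], np.float32)
        r = L.local_region(x, mask)
        assert np.allclose(r.data[0, 0], [[0.25, 1], [1, 1]])

    def test_elementwise_matches_loop_oracle(self, rng):
        x = _img(rng)
        mask = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        r = L.local_region(x, mask).data
        for c in range(3):
            for i in range(8):
                for j in range(8):
                    m = mask[0, 0, i, j]
                    assert r[0, c, i, j] == pytest.approx(x[0, c, i, j] * m + (1 - m))


class TestAdversarial:
    def test_perfect_discriminator_zero_loss(self):
        d_loss, _ = L.adversarial_losses(np.ones((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)))
        assert d_loss.item() == 0.0

    def test_fooled_discriminator_loss_one(self):
        d_loss, _ = L.adversarial_losses(np.ones((1, 1, 4, 4)), np.ones((1, 1, 4, 4)))
        assert d_loss.item() == pytest.approx(1.0)

    def test_generator_term_half_scores(self):
        g = L.generator_adversarial(np.full((1, 1, 4, 4), 0.5))
        assert g.item() == pytest.approx(0.25)


class TestL1:
    def test_identical_zero(self, rng):
        x = _img(rng)
        mask = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        g, l = L.l1_losses(x, x, mask)
        assert g.item() == 0.0 and l.item() == 0.0

    def test_constant_shift(self, rng):
        x = rng.random((1, 3, 8, 8)).astype(np.float32) * 0.5
        g, _ = L.l1_losses(x, x + 0.1, np.ones((1, 1, 8, 8), np.float32))
        assert g.item() == pytest.approx(0.1, abs=1e-6)

    def test_background_difference_invisible_locally(self, rng):
        x = _img(rng)
        mask = np.zeros((1, 1, 8, 8), np.float32)
        mask[0, 0, 2:5, 2:5] = 1
        y = x.copy()
        y[0, :, 6:, 6:] += 0.3  # differ only outside the mask
        g, l = L.l1_losses(x, y, mask)
        assert l.item() == pytest.approx(0.0, abs=1e-7)
        assert g.item() > 0


class TestPerceptualStyle:
    def test_identical_inputs_zero(self, rng):
        x = _img(rng)
        per, sty, _, _ = L.perceptual_and_style(x, x, L.IdentityFeatures())
        assert per.item() == 0.0 and sty.item() == 0.0

    def test_identity_phi_reduces_to_l1(self, rng):
        a, b = _img(rng), _img(rng)
        per, _, _, _ = L.perceptual_and_style(a, b, L.IdentityFeatures())
        assert per.item() == pytest.approx(np.abs(a - b).mean(), rel=1e-6)

    def test_gram_of_constant_map(self):
        c, n = 0.7, 16
        feat = np.full((1, 1, 4, 4), c, np.float32)
        g = L.gram_matrix(feat)
        assert g.data[0, 0, 0] == pytest.approx(c * c * n, rel=1e-6)

    def test_gram_matches_hand_loop(self, rng):
        feat = rng.random((1, 3, 4, 4)).astype(np.float32)
        g = L.gram_matrix(feat).data[0]
        flat = feat[0].reshape(3, -1)
        for i in range(3):
            for j in range(3):
                assert g[i, j] == pytest.approx(float(flat[i] @ flat[j]), rel=1e-5)

    def test_unknown_layer_rejected(self, rng):
        x = _img(rng)
        with pytest.raises(ValueError):
            L.perceptual_and_style(x, x, L.IdentityFeatures(), layers=["missing"])

    def test_random_conv_features_frozen_and_deterministic(self, rng):
        x = _img(rng, h=16, w=16)
        phi1 = L.RandomConvFeatures(seed=5)
        phi2 = L.RandomConvFeatures(seed=5)
        f1, f2 = phi1(x), phi2(x)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.data, b.data)
        assert not any(p.requires_grad for p in phi1.parameters())


class TestTotalLoss:
    def test_all_zero(self):
        assert L.total_inpaint_loss(0, 0, 0, 0, 0, 0) == 0.0

    def test_printed_weights_hand_value(self):
        # 0.02*(1+1) + 1 + 1 + 0.1 + 150 = 152.14
        assert L.total_inpaint_loss(1, 1, 1, 1, 1, 1) == pytest.approx(152.14)

    def test_only_adversarial(self):
        assert L.total_inpaint_loss(1, 1, 0, 0, 0, 0) == pytest.approx(0.04)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            L.total_inpaint_loss(-0.1, 0, 0, 0, 0, 0)

    @pytest.mark.parametrize(
        "name,weight",
        [("adv_g", 0.02), ("adv_l", 0.02), ("l1_g", 1.0), ("l1_l", 1.0),
         ("perceptual", 0.1), ("style", 150.0)],
    )
    def test_linear_in_each_component(self, name, weight):
        base = dict(adv_g=0.3, adv_l=0.2, l1_g=0.5, l1_l=0.4,
                    perceptual=0.1, style=0.01)
        lo = L.total_inpaint_loss(**base)
        bumped = dict(base)
        bumped[name] += 1.0
        hi = L.total_inpaint_loss(**bumped)
        assert hi - lo == pytest.approx(weight, rel=1e-9)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            L.LossWeights(style=-1.0)


class TestSegLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.array([[[[1, 0], [0, 1]]]], np.float32)
        p = np.clip(t, 1e-6, 1 - 1e-6)
        assert L.seg_loss(p, t).item() < 1e-4

    def test_hand_value_half_probability(self):
        # BCE = ln2; soft dice = 0.5 -> loss = 0.5*ln2 + 0.5
        t = np.zeros((1, 1, 2, 2), np.float32)
        t[0, 0, 0] = 1  # half the pixels positive
        p = np.full((1, 1, 2, 2), 0.5, np.float32)
        expected = 0.5 * np.log(2) + 0.5
        assert L.seg_loss(p, t).item() == pytest.approx(expected, rel=1e-4)

    def test_lambda_zero_is_pure_dice(self, rng):
        t = (rng.random((1, 2, 4, 4)) > 0.5).astype(np.float32)
        p = rng.random((1, 2, 4, 4)).astype(np.float32)
        eps = 1e-6
        inter = (p * t).sum()
        dice = 1 - (2 * inter + eps) / (p.sum() + t.sum() + eps)
        assert L.seg_loss(p, t, lam=0.0).item() == pytest.approx(float(dice), rel=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            L.seg_loss(np.zeros((1, 2, 4, 4)), np.zeros((1, 2, 4, 5)))


def test_loss_report_total_identity(rng):
    report = L.build_loss_report(0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    w = L.LossWeights()
    expected = (w.adv * (0.1 + 0.2) + w.l1_g * 0.3 + w.l1_l * 0.4
                + w.perceptual * 0.5 + w.style * 0.6)
    assert report.total == pytest.approx(expected, rel=1e-9)
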