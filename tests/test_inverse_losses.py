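import itertools

import numpy as np
import pytest

from cardiotwin.inverse.autodiff import Parameter, Tensor
from cardiotwin.inverse.losses import (TrainingConfig, chamfer,
                                       chamfer_recon_loss, compactness_loss,
                                       kl_gaussian, qrs_recon_loss, seg_loss,
                                       size_loss, soft_dice, spatial_loss,
                                       total_inference_loss, vae_loss)


class TestChamfer:
    def test_identity_zero(self):
        pts = np.random.default_rng(0).standard_normal((30, 3))
        assert chamfer(pts, pts) == 0.0

    def test_brute_force_oracle_five_points(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        fwd = np.mean([min(np.sum((p - q) ** 2) for q in b) for p in a])
        bwd = np.mean([min(np.sum((p - q) ** 2) for p in a) for q in b])
        assert chamfer(a, b) == pytest.approx(fwd + bwd)

    def test_recon_loss_hand_arithmetic(self):
        """alpha = 5, coarse chamfer 0.1, dense chamfer 0.2 -> 1.1."""
        inp = np.array([[0.0, 0.0, 0.0]])
        coarse = np.array([[np.sqrt(0.05), 0.0, 0.0]])   # chamfer 2*0.05
        dense = np.array([[np.sqrt(0.10), 0.0, 0.0]])    # chamfer 2*0.10
        val = chamfer_recon_loss([inp], [coarse], [dense], alpha=5.0)
        assert val == pytest.approx(1.1, abs=1e-9)

    def test_perfect_reconstruction_zero(self):
        pts = np.random.default_rng(2).standard_normal((16, 3))
        assert chamfer_recon_loss([pts], [pts], [pts], alpha=5.0) == 0.0

    def test_empty_class_warns_and_contributes_zero(self):
        pts = np.ones((4, 3))
        with pytest.warns(UserWarning):
            val = chamfer_recon_loss([pts, np.empty((0, 3))],
                                     [pts, pts], [pts, pts], alpha=5.0)
        assert val == 0.0


class TestQRSReconLoss:
    def test_identical_zero(self):
        rng = np.random.default_rng(0)
        q = rng.standard_normal((8, 64))
        assert qrs_recon_loss(q, q) == 0.0

    def test_constant_offset_mse_term(self):
        q = np.zeros((2, 16))
        delta = 0.37
        val = qrs_recon_loss(q, q + delta)
        # MSE term is exactly delta^2; DTW adds a non-negative remainder
        assert val >= delta ** 2
        assert val - delta ** 2 == pytest.approx(delta, abs=1e-9)

    def test_eval_dtw_matches_analysis_module(self):
        from cardiotwin.qrs_analysis import dtw_distance

        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        val = qrs_recon_loss(a[None], b[None])
        mse = np.mean((a - b) ** 2)
        assert val - mse == pytest.approx(dtw_distance(a, b, lam_dur=0.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qrs_recon_loss(np.zeros((2, 8)), np.zeros((2, 9)))


class TestKL:
    def test_posterior_equals_prior_zero(self):
        assert kl_gaussian(np.zeros(4), np.zeros(4)) == 0.0

    def test_unit_mean_closed_form(self):
        """1-D, mu = 1, sigma = 1: KL = 0.5."""
        assert kl_gaussian(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_matches_monte_carlo(self):
        """Closed form vs Monte-Carlo estimate within 2 % at 1e5 samples."""
        mu, logvar = 0.7, np.log(0.6)
        rng = np.random.default_rng(0)
        x = rng.normal(mu, np.sqrt(0.6), size=100_000)
        logq = -0.5 * ((x - mu) ** 2 / 0.6 + np.log(2 * np.pi * 0.6))
        logp = -0.5 * (x ** 2 + np.log(2 * np.pi))
        mc = float(np.mean(logq - logp))
        cf = kl_gaussian(np.array([mu]), np.array([logvar]))
        assert abs(cf - mc) / cf < 0.02

    def test_lambda_kl_scaling(self):
        cfg = TrainingConfig()
        assert cfg.lam_kl == 0.01
        assert vae_loss(0.0, 0.0, 3.0, cfg) == pytest.approx(0.03)


class TestSegLoss:
    def test_one_hot_correct_is_zero(self):
        gt = np.array([0, 1, 2, 1])
        p = np.eye(3)[gt]
        assert seg_loss(p, gt) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_prediction_ce_ln3(self):
        gt = np.array([0, 1, 2])
        p = np.full((3, 3), 1 / 3)
        val = seg_loss(p, gt, lam_dice=0.0)
        assert val == pytest.approx(np.log(3.0))

    def test_soft_dice_toy_hand_value(self):
        """4 points, two classes present; Dice computed by hand."""
        gt = np.array([0, 0, 1, 1])
        p = np.array([[1.0, 0.0, 0.0],
                      [0.5, 0.5, 0.0],
                      [0.0, 1.0, 0.0],
                      [0.0, 1.0, 0.0]])
        # class 0: inter 1.5, sums 1.5 + 2 -> dice 6/7
        # class 1: inter 2.0, sums 2.5 + 2 -> dice 8/9
        # class 2: empty/empty -> eps convention gives 1
        expect = (6 / 7 + 8 / 9 + 1.0) / 3
        assert soft_dice(p, gt) == pytest.approx(expect, abs=1e-6)

    def test_unnormalized_probs_rejected(self):
        with pytest.raises(ValueError):
            seg_loss(np.full((3, 3), 0.5), np.array([0, 1, 2]))


class TestCountingLosses:
    def test_compactness_zero_at_shared_centroid(self):
        gt = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        pred = np.zeros((3, 3))   # all at the common centroid
        assert compactness_loss(pred, gt) == 0.0

    def test_compactness_hand_value_one(self):
        """One predicted point at distance d_max from the ground-truth
        centroid: loss = (0 + d_max) / d_max = 1."""
        gt = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
        pred = np.array([[2.0, 0.0, 0.0]])
        assert compactness_loss(pred, gt) == pytest.approx(1.0)

    def test_compactness_scale_invariant(self):
        rng = np.random.default_rng(0)
        gt = rng.standard_normal((10, 3))
        pred = rng.standard_normal((6, 3))
        a = compactness_loss(pred, gt)
        b = compactness_loss(2 * pred, 2 * gt)
        assert a == pytest.approx(b)

    def test_compactness_degenerate_gt(self):
        with pytest.warns(UserWarning):
            assert compactness_loss(np.ones((2, 3)), np.ones((3, 3))) == 0.0

    def test_size_loss_values(self):
        assert size_loss(10, 10) == 0.0
        assert size_loss(20, 10) == pytest.approx(1.0)
        assert size_loss(5, 10) == pytest.approx(0.5)   # absolute value
        with pytest.warns(UserWarning):
            assert size_loss(5, 0) == 0.0

    def test_spatial_loss_values(self):
        assert spatial_loss(0, 50) == 0.0
        assert spatial_loss(10, 50) == pytest.approx(0.2)
        assert spatial_loss(0, 0) == 0.0

    def test_total_with_unit_parts_and_default_weights(self):
        cfg = TrainingConfig()
        assert total_inference_loss(1, 1, 1, 1, 1, cfg) == pytest.approx(5.0)
        assert total_inference_loss(0, 0, 0, 0, 0, cfg) == 0.0


class TestAutodiffConsistency:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        W = Parameter(rng.standard_normal((4, 3)))
        x = Tensor(rng.standard_normal((6, 4)))

        def f():
            h = (x @ W).tanh()
            return (h ** 2).mean() + h.max(axis=1).sum() * 0.1

        loss = f()
        loss.backward()
        g = W.grad.copy()
        eps = 1e-6
        for i in range(4):
            for j in range(3):
                W.data[i, j] += eps
                up = float(f().data)
                W.data[i, j] -= 2 * eps
                dn = float(f().data)
                W.data[i, j] += eps
                assert g[i, j] == pytest.approx((up - dn) / (2 * eps),
                                                abs=1e-6)

    def test_soft_dtw_divergence_near_zero_on_match(self):
        from cardiotwin.inverse.losses import soft_dtw_div_ad

        rng = np.random.default_rng(1)
        sig = rng.standard_normal((3, 12))
        val = soft_dtw_div_ad(Parameter(sig.copy()), sig, gamma=1.0)
        assert abs(float(val.data)) < 1e-9

    def test_chamfer_ad_matches_reference(self):
        from cardiotwin.inverse.losses import chamfer_ad

        rng = np.random.default_rng(2)
        a = rng.standard_normal((7, 3))
        b = rng.standard_normal((9, 3))
        assert float(chamfer_ad(Parameter(a), b).data) == pytest.approx(
            chamfer(a, b))
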