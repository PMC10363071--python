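"""Closed-form loss values, invariances and gradient sanity."""

import numpy as np
import pytest

from synthce.losses import (LossWeights, bce_disc_loss, bce_gen_loss,
                            cycle_loss, identity_loss, lsgan_disc_loss,
                            lsgan_gen_loss, roi_weighted_l1)
from synthce.nn import Tensor

SHAPE = (4, 4, 4)


class TestRoiWeightedL1:
    def _mask(self):
        fg = np.zeros(SHAPE)
        fg[:2] = 1.0
        return fg

    def test_zero_for_perfect_prediction(self):
        x = np.random.default_rng(0).random(SHAPE)
        for mu in (0.0, 0.2, 1.0):
            assert float(roi_weighted_l1(x, x, self._mask(), mu)) == 0.0

    def test_uniform_unit_error_gives_one(self):
        t = np.zeros(SHAPE)
        p = np.ones(SHAPE)
        for mu in (0.0, 0.3, 1.0):
            assert float(roi_weighted_l1(t, p, self._mask(), mu)) \
                == pytest.approx(1.0)

    def test_foreground_only_error_weighted_by_mu(self):
        fg = self._mask()
        t = np.zeros(SHAPE)
        p = fg.copy()  # error 1 on foreground, 0 on background
        assert float(roi_weighted_l1(t, p, fg, 0.2)) == pytest.approx(0.2)

    def test_degenerate_mu_reduces_to_single_region(self):
        fg = self._mask()
        rng = np.random.default_rng(1)
        t, p = rng.random(SHAPE), rng.random(SHAPE)
        err = np.abs(t - p)
        assert float(roi_weighted_l1(t, p, fg, 1.0)) \
            == pytest.approx(err[fg > 0].mean())
        assert float(roi_weighted_l1(t, p, fg, 0.0)) \
            == pytest.approx(err[fg == 0].mean())

    def test_permutation_invariant_within_regions(self):
        fg = self._mask()
        rng = np.random.default_rng(2)
        t, p = rng.random(SHAPE), rng.random(SHAPE)
        ref = float(roi_weighted_l1(t, p, fg, 0.2))
        # permute the foreground voxels of both arrays identically
        idx = np.where(fg.ravel() > 0)[0]
        perm = rng.permutation(idx)
        t2, p2 = t.ravel().copy(), p.ravel().copy()
        t2[idx], p2[idx] = t.ravel()[perm], p.ravel()[perm]
        assert float(roi_weighted_l1(t2.reshape(SHAPE), p2.reshape(SHAPE),
                                     fg, 0.2)) == pytest.approx(ref)

    def test_empty_foreground_contributes_zero(self):
        t = np.zeros(SHAPE)
        p = np.ones(SHAPE)
        assert float(roi_weighted_l1(t, p, np.zeros(SHAPE), 0.2)) \
            == pytest.approx(0.8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            roi_weighted_l1(np.zeros((2, 2, 2)), np.zeros(SHAPE),
                            np.zeros(SHAPE), 0.2)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(mu=1.5)
        with pytest.raises(ValueError):
            LossWeights(lam=-1.0)


class TestAdversarialLosses:
    def test_bce_disc_at_half_scores(self):
        half = np.full(SHAPE, 0.5)
        assert float(bce_disc_loss(half, half)) \
            == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_bce_disc_perfect_limit(self):
        ones = np.ones(SHAPE)
        zeros = np.zeros(SHAPE)
        assert float(bce_disc_loss(ones, zeros)) == pytest.approx(0.0, abs=1e-5)

    def test_bce_gen_at_half_scores(self):
        assert float(bce_gen_loss(np.full(SHAPE, 0.5))) \
            == pytest.approx(np.log(2), rel=1e-9)

    def test_lsgan_disc_optimum_is_zero(self):
        assert float(lsgan_disc_loss(np.ones(SHAPE), np.zeros(SHAPE))) == 0.0

    def test_lsgan_gen_optimum_is_zero(self):
        assert float(lsgan_gen_loss(np.ones(SHAPE))) == 0.0

    def test_lsgan_disc_at_half_scores(self):
        half = np.full(SHAPE, 0.5)
        assert float(lsgan_disc_loss(half, half)) == pytest.approx(0.5)

    def test_lsgan_rejects_nonfinite_scores(self):
        with pytest.raises(ValueError):
            lsgan_gen_loss(np.full(SHAPE, np.inf))


class TestCycleAndIdentity:
    def test_identity_generators_give_zero(self):
        x = np.random.default_rng(0).random(SHAPE)
        y = np.random.default_rng(1).random(SHAPE)
        assert float(cycle_loss(x, x, y, y)) == 0.0
        assert float(identity_loss(x, x, y, y)) == 0.0

    def test_constant_offset_terms(self):
        x = np.random.default_rng(2).random(SHAPE)
        y = np.random.default_rng(3).random(SHAPE)
        assert float(cycle_loss(x, x + 0.1, y, y)) == pytest.approx(0.1)
        assert float(identity_loss(x, x, y, y + 0.2)) == pytest.approx(0.2)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(4)
        x, xr, y, yr = (rng.random(SHAPE) for _ in range(4))
        expected = np.mean(np.abs(x - xr)) + np.mean(np.abs(y - yr))
        assert float(cycle_loss(x, xr, y, yr)) == pytest.approx(expected,
                                                                rel=1e-12)


class TestGradientSanity:
    """Each loss decreases after one descent step on a one-parameter
    scalar-multiplier generator pred = a * x."""

    @pytest.mark.parametrize("loss_name", ["roi_l1", "lsgan_gen", "bce_gen",
                                           "cycle"])
    def test_one_gradient_step_decreases_loss(self, loss_name):
        rng = np.random.default_rng(5)
        x = Tensor(rng.random(SHAPE) + 0.5)
        target = x * 2.0
        fg = np.zeros(SHAPE)
        fg[:2] = 1.0
        a = Tensor(np.array(1.0), requires_grad=True)

        def compute():
            pred = a * x
            if loss_name == "roi_l1":
                return roi_weighted_l1(target, pred, fg, 0.2)
            if loss_name == "lsgan_gen":
                return lsgan_gen_loss(pred - 1.0)
            if loss_name == "bce_gen":
                return bce_gen_loss((pred * 0.4).clip(0.01, 0.99))
            return cycle_loss(target, pred, target, pred)

        loss0 = compute()
        loss0.backward()
        assert np.isfinite(a.grad)
        a.data = a.data - 0.05 * np.sign(a.grad)
        assert float(compute()) < float(loss0)
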