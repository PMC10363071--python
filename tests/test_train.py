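"""Training machinery: replay buffer, differentiable augmentation, the four
paradigms at smoke scale, and the downstream segmentation trainer."""

import numpy as np
import pandas as pd
import pytest

from synthce.losses import bce_gen_loss, roi_weighted_l1
from synthce.nn import Tensor
from synthce.train import (DiffAugmentParams, ExperimentConfig, ImageBuffer,
                           buffer_sample, diff_augment, train,
                           train_segmentation)

TINY = dict(patch_size=16, gen_layers=2, gen_channels=2,
            disc_layers=2, disc_channels=2)


class TestImageBuffer:
    def test_fill_phase_returns_own_inputs(self):
        buf = ImageBuffer(capacity=50)
        rng = np.random.default_rng(0)
        for i in range(50):
            img = np.full((2, 2), float(i))
            assert buffer_sample(buf, img, rng) is img
        assert len(buf.stored) == 50

    def test_capacity_never_exceeded(self):
        buf = ImageBuffer(capacity=50)
        rng = np.random.default_rng(1)
        for i in range(2000):
            buffer_sample(buf, np.array([float(i)]), rng)
            assert len(buf.stored) <= 50

    def test_long_run_fresh_return_rate_is_half(self):
        buf = ImageBuffer(capacity=50)
        rng = np.random.default_rng(2)
        for i in range(50):
            buffer_sample(buf, np.array([float(i)]), rng)
        n = 10_000
        fresh = 0
        for i in range(n):
            img = np.array([float(50 + i)])
            out = buffer_sample(buf, img, rng)
            fresh += out is img
        # binomial(n, 0.5): 3 standard errors
        se = 0.5 / np.sqrt(n)
        assert abs(fresh / n - 0.5) < 3 * se


class TestDiffAugment:
    def _batch(self, n=2, size=8):
        rng = np.random.default_rng(3)
        return [Tensor(rng.random((1, 1, size, size, size))) for _ in range(n)]

    def test_zero_magnitudes_is_identity(self):
        imgs = self._batch()
        params = DiffAugmentParams(shift=(0, 0, 0), cutout_corner=None,
                                   cutout_size=0, gain=1.0, offset=0.0)
        out = diff_augment(imgs, np.random.default_rng(0), params=params)
        for a, b in zip(out, imgs):
            assert np.array_equal(a.data, b.data)

    def test_translation_is_shifted_copy_with_zero_fill(self):
        [img] = self._batch(1)
        params = DiffAugmentParams(shift=(2, 0, -1), cutout_corner=None,
                                   cutout_size=0, gain=1.0, offset=0.0)
        [out] = diff_augment([img], np.random.default_rng(0), params=params)
        assert np.array_equal(out.data[0, 0, 2:, :, :-1],
                              img.data[0, 0, :-2, :, 1:])
        assert (out.data[0, 0, :2] == 0).all()

    def test_cutout_zeroes_one_contiguous_block(self):
        size = 8
        ones = [Tensor(np.ones((1, 1, size, size, size)))]
        params = DiffAugmentParams(shift=(0, 0, 0), cutout_corner=(2, 3, 1),
                                   cutout_size=2, gain=1.0, offset=0.0)
        [out] = diff_augment(ones, np.random.default_rng(0), params=params)
        zeros = np.argwhere(out.data[0, 0] == 0)
        assert len(zeros) == 8  # 2^3 block
        assert (zeros.max(axis=0) - zeros.min(axis=0) == 1).all()

    def test_shared_transform_across_batch(self):
        [img] = self._batch(1)
        twin = Tensor(img.data.copy())
        out = diff_augment([img, twin], np.random.default_rng(7))
        # identical inputs must stay identical under the shared transform
        assert np.array_equal(out[0].data, out[1].data)
        assert not np.array_equal(out[0].data, img.data)  # transform applied


class TestParadigms:
    def test_supervised_loss_decreases(self, small_cohort):
        cfg = ExperimentConfig.for_paradigm(
            "supervised_phase", steps=120, seed=1, lr_gen=2e-3, **TINY)
        res = train(cfg, small_cohort[:2])
        log = res.log["loss_roi"]
        assert log.iloc[-20:].mean() < log.iloc[:20].mean()

    def test_identical_config_and_seed_is_deterministic(self, small_cohort):
        cfg = ExperimentConfig.for_paradigm(
            "supervised_phase", steps=25, seed=9, **TINY)
        a = train(cfg, small_cohort[:2])
        b = train(cfg, small_cohort[:2])
        assert a.log["loss_roi"].iloc[-1] == b.log["loss_roi"].iloc[-1]

    def test_baseline_trains_one_generator_per_phase(self, small_cohort):
        cfg = ExperimentConfig.for_paradigm(
            "supervised_baseline", steps=6, seed=2, **TINY)
        res = train(cfg, small_cohort[:2])
        assert set(res.generators) == {1, 2}
        assert not res.generators[1].spec.conditioned

    def test_pix2pix_smoke_runs_and_logs_all_terms(self, small_cohort):
        cfg = ExperimentConfig.for_paradigm(
            "adversarial_supervised", steps=8, seed=3, **TINY)
        res = train(cfg, small_cohort[:2])
        assert {"loss_d", "loss_g", "loss_adv", "loss_roi"} <= set(res.log)
        assert np.isfinite(res.log.to_numpy()[:, 2:].astype(float)).all()
        assert res.generators["conditioned"].spec.dropout_decoder_layers == 3

    def test_cyclegan_smoke_runs_and_logs_all_terms(self, small_cohort):
        cfg = ExperimentConfig.for_paradigm(
            "cycle_adversarial", steps=4, seed=4, **TINY)
        res = train(cfg, small_cohort[:2])
        assert {"loss_cyc", "loss_id"} <= set(res.log)
        assert np.isfinite(res.log["loss_g"]).all()
        assert set(res.generators) == {"forward", "backward"}

    def test_unknown_paradigm_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(paradigm="nonsense")

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            train(ExperimentConfig.for_paradigm("supervised_phase"), [])


def test_zero_adversarial_limit_reduces_to_supervised_update():
    """As lambda -> inf, the normalised adversarial-with-supervision generator
    gradient converges to the pure supervised-gradient direction (checked on a
    one-parameter scalar generator)."""
    rng = np.random.default_rng(0)
    x = Tensor(rng.random((4, 4, 4)))
    target = x * 1.5
    fg = np.zeros((4, 4, 4))
    fg[:2] = 1.0

    def grad_total(lam):
        a = Tensor(np.array(1.0), requires_grad=True)
        pred = a * x
        score = (pred * 0.3).clip(0.01, 0.99)  # frozen 'discriminator'
        loss = (bce_gen_loss(score) + lam * roi_weighted_l1(target, pred, fg, 0.2)) * (1.0 / lam)
        loss.backward()
        return float(a.grad)

    def grad_supervised():
        a = Tensor(np.array(1.0), requires_grad=True)
        roi_weighted_l1(target, a * x, fg, 0.2).backward()
        return float(a.grad)

    g_sup = grad_supervised()
    assert abs(grad_total(1e8) - g_sup) < 1e-6 * abs(g_sup) + 1e-12


class TestSegmentationTrainer:
    def _patches(self, n=12, size=16, empty=False):
        rng = np.random.default_rng(5)
        imgs, masks = [], []
        for _ in range(n):
            mask = np.zeros((size, size))
            if not empty:
                c = rng.integers(4, size - 4, size=2)
                r = rng.integers(2, 4)
                yy, xx = np.ogrid[0:size, 0:size]
                mask[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r ** 2] = 1.0
            img = 0.2 + 0.6 * mask + rng.normal(0, 0.05, (size, size))
            imgs.append(np.clip(img, 0, 1))
            masks.append(mask)
        return imgs, masks

    def test_dice_improves_over_epochs(self):
        imgs, masks = self._patches()
        net, log = train_segmentation(imgs, masks, minibatch=4, epochs=4,
                                      first_channels=4, n_layers=2, seed=0)
        assert log["dice"].iloc[-1] > log["dice"].iloc[0]

    def test_all_background_converges_to_empty_predictions(self):
        imgs, masks = self._patches(empty=True)
        net, log = train_segmentation(imgs, masks, lr=1e-2, minibatch=4,
                                      epochs=30, first_channels=2,
                                      n_layers=2, seed=0)
        # empty-vs-empty Dice convention: 1.0
        assert log["dice"].iloc[-1] == pytest.approx(1.0)

    def test_seeded_determinism(self):
        imgs, masks = self._patches(n=6)
        _, a = train_segmentation(imgs, masks, minibatch=3, epochs=2,
                                  first_channels=2, n_layers=2, seed=3)
        _, b = train_segmentation(imgs, masks, minibatch=3, epochs=2,
                                  first_channels=2, n_layers=2, seed=3)
        assert a["bce"].iloc[-1] == b["bce"].iloc[-1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_segmentation([], [])
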