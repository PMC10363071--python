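"""The three training paradigms and the downstream segmentation trainer.

* ``supervised_baseline`` — one unconditioned U-Net generator per contrast
  phase, ROI-weighted L1 loss, standard affine augmentation.
* ``supervised_phase`` — a single phase-conditioned generator, sampling the
  target phase uniformly per step.
* ``adversarial_supervised`` — Pix2Pix-style: BCE adversarial pair plus
  lambda * L_ROI supervision, dropout noise in the first three decoder
  layers kept on at train and inference, differentiable augmentation of
  every (real and generated) image the discriminator sees.
* ``cycle_adversarial`` — CycleGAN-style unpaired training: forward and
  backward generator/discriminator pairs, least-squares adversarial terms,
  cycle-consistency (weight lambda) and identity (lambda/2) losses, and a
  50-image buffer of past generator outputs for discriminator updates.

Training is step-based with minibatch 1 and per-step random patch sampling;
all randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ctdata import AugmentRanges, PatchSample, augment_supervised, extract_patches, window_normalise
from .losses import (LossWeights, bce_disc_loss, bce_gen_loss, cycle_loss,
                     identity_loss, lsgan_disc_loss, lsgan_gen_loss,
                     roi_weighted_l1)
from .nets import (DiscriminatorSpec, GeneratorSpec, PatchDiscriminator,
                   SegUNet2d, UNetGenerator)
from .nn import Adam, Tensor
from .phantom import CME, NGE, SubjectCase

__all__ = [
    "PARADIGMS", "ExperimentConfig", "ImageBuffer", "buffer_sample",
    "diff_augment", "DiffAugmentParams", "train", "TrainResult",
    "train_segmentation", "TrainingDiverged",
]

PARADIGMS = ("supervised_baseline", "supervised_phase",
             "adversarial_supervised", "cycle_adversarial")

# Tuned hyperparameter defaults per paradigm.
_PARADIGM_DEFAULTS = {
    "supervised_baseline": dict(lr_gen=1.0e-4, lr_disc=0.0,
                                weights=LossWeights(mu=0.2, lam=0.0),
                                dropout_decoder_layers=0),
    "supervised_phase": dict(lr_gen=1.0e-4, lr_disc=0.0,
                             weights=LossWeights(mu=0.2, lam=0.0),
                             dropout_decoder_layers=0),
    "adversarial_supervised": dict(lr_gen=3.5e-4, lr_disc=2.0e-5,
                                   weights=LossWeights(mu=0.1, lam=720.0),
                                   dropout_decoder_layers=3),
    "cycle_adversarial": dict(lr_gen=2.0e-4, lr_disc=2.0e-4,
                              weights=LossWeights(mu=0.2, lam=10.0),
                              dropout_decoder_layers=3),
}


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class ExperimentConfig:
    paradigm: str = "supervised_phase"
    steps: int = 500
    patch_size: int = 64
    minibatch: int = 1
    seed: int = 0
    lr_gen: float = 1.0e-4
    lr_disc: float = 2.0e-5
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    weights: LossWeights = field(default_factory=LossWeights)
    buffer_capacity: int = 50
    gen_layers: int = 5
    gen_channels: int = 32
    disc_layers: int = 3
    disc_channels: int = 16
    dropout_decoder_layers: int = 0
    augment: bool = True
    augment_ranges: AugmentRanges = field(default_factory=AugmentRanges)
    foreground_bias: float = 0.5
    log_every: int = 1

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}; "
                             f"choose from {PARADIGMS}")
        if min(self.steps, self.patch_size, self.minibatch) < 1:
            raise ValueError("steps, patch_size, minibatch must be positive")
        if self.lr_gen <= 0:
            raise ValueError("lr_gen must be positive")

    @classmethod
    def for_paradigm(cls, paradigm: str, **overrides) -> "ExperimentConfig":
        base = dict(_PARADIGM_DEFAULTS[paradigm])
        base.update(overrides)
        return cls(paradigm=paradigm, **base)


class ImageBuffer:
    """Pool of up to ``capacity`` previously generated images; discriminator
    updates draw from it to damp oscillation (the classic 50-image replay
    buffer from unpaired adversarial training)."""

    def __init__(self, capacity: int = 50):
        self.capacity = capacity
        self.stored: list[np.ndarray] = []

    def sample(self, new_image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if len(self.stored) < self.capacity:
            self.stored.append(np.array(new_image, copy=True))
            return new_image
        if rng.random() < 0.5:
            return new_image
        idx = int(rng.integers(0, self.capacity))
        old = self.stored[idx]
        self.stored[idx] = np.array(new_image, copy=True)
        return old


def buffer_sample(buffer: ImageBuffer, new_image: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    return buffer.sample(new_image, rng)


@dataclass(frozen=True)
class DiffAugmentParams:
    """One jointly drawn discriminator-input transform: integer translation
    (zero-filled), one square/cubic cut-out, and affine intensity/contrast
    jitter.  All operations are differentiable in the pixel values."""
    shift: tuple[int, ...]
    cutout_corner: tuple[int, ...] | None
    cutout_size: int
    gain: float
    offset: float

    @classmethod
    def draw(cls, rng: np.random.Generator, spatial: tuple[int, ...],
             translate_frac: float = 0.125, cutout_frac: float = 0.25,
             jitter: float = 0.1) -> "DiffAugmentParams":
        max_shift = [max(1, int(s * translate_frac)) for s in spatial]
        shift = tuple(int(rng.integers(-m, m + 1)) for m in max_shift)
        csize = int(round(spatial[-1] * cutout_frac))
        if csize > 0:
            corner = tuple(int(rng.integers(0, s - csize + 1)) for s in spatial)
        else:
            corner = None
        return cls(shift=shift, cutout_corner=corner, cutout_size=csize,
                   gain=float(rng.uniform(1 - jitter, 1 + jitter)),
                   offset=float(rng.uniform(-jitter, jitter)))


def _apply_diff_augment(x: Tensor, p: DiffAugmentParams) -> Tensor:
    nd = x.ndim - 2
    spatial = x.shape[2:]
    # integer translation via pad + slice (zero fill)
    pads = [(0, 0), (0, 0)]
    sls = [slice(None), slice(None)]
    for d, s in enumerate(p.shift):
        if s >= 0:
            pads.append((s, 0))
            sls.append(slice(0, spatial[d]))
        else:
            pads.append((0, -s))
            sls.append(slice(-s, -s + spatial[d]))
    x = x.pad(pads)[tuple(sls)]
    if p.cutout_corner is not None and p.cutout_size > 0:
        mask = np.ones((1, 1) + tuple(spatial))
        region = (0, 0) + tuple(
            slice(min(c, spatial[d] - p.cutout_size),
                  min(c, spatial[d] - p.cutout_size) + p.cutout_size)
            for d, c in enumerate(p.cutout_corner))
        mask[region] = 0.0
        x = x * Tensor(mask)
    return x * p.gain + p.offset


def diff_augment(images: list[Tensor], rng: np.random.Generator,
                 params: DiffAugmentParams | None = None,
                 **draw_kw) -> list[Tensor]:
    """Apply one shared random transform to every image in the batch, so real
    and generated discriminator inputs within a step match."""
    images = [x if isinstance(x, Tensor) else Tensor(x) for x in images]
    if params is None:
        params = DiffAugmentParams.draw(rng, images[0].shape[2:], **draw_kw)
    return [_apply_diff_augment(x, params) for x in images]


@dataclass
class TrainResult:
    generators: dict   # phase -> UNetGenerator, or "conditioned"/"forward"...
    discriminators: dict
    log: pd.DataFrame
    config: ExperimentConfig

    def generator_for(self, phase: int):
        if "conditioned" in self.generators:
            return self.generators["conditioned"]
        if "forward" in self.generators:
            return self.generators["forward"]
        return self.generators[phase]

    def save_log(self, path: str | Path):
        self.log.to_csv(path, index=False)


def _windowed(case: SubjectCase):
    return {
        None: window_normalise(case.nce, provenance=case.subject_id + "/nce"),
        CME: window_normalise(case.cme, provenance=case.subject_id + "/cme"),
        NGE: window_normalise(case.nge, provenance=case.subject_id + "/nge"),
    }


def _sample_patch(cohort_w, cohort, phase, cfg, rng) -> PatchSample:
    i = int(rng.integers(0, len(cohort)))
    w = cohort_w[i]
    [patch] = extract_patches(
        w[None], w[phase], cohort[i].roi_mask, n=1,
        patch_size=cfg.patch_size, rng_seed=rng, phase=phase,
        foreground_bias=cfg.foreground_bias)
    return patch

def _check_finite(value: float, step: int, label: str):
    if not np.isfinite(value):
        raise TrainingDiverged(f"{label} became non-finite at step {step}")


def _gen_spec(cfg: ExperimentConfig, conditioned: bool) -> GeneratorSpec:
    return GeneratorSpec(n_layers=cfg.gen_layers,
                         first_channels=cfg.gen_channels,
                         conditioned=conditioned,
                         dropout_decoder_layers=cfg.dropout_decoder_layers)


def _disc_spec(cfg: ExperimentConfig, conditioned: bool) -> DiscriminatorSpec:
    return DiscriminatorSpec(n_layers=cfg.disc_layers,
                             first_channels=cfg.disc_channels,
                             conditioned=conditioned)


def train(config: ExperimentConfig, cohort: list[SubjectCase]) -> TrainResult:
    """Dispatch to the configured paradigm. Raises TrainingDiverged on
    non-finite losses."""
    if not cohort:
        raise ValueError("empty cohort")
    ss = np.random.SeedSequence(entropy=config.seed)
    dispatch = {
        "supervised_baseline": _train_supervised_baseline,
        "supervised_phase": _train_supervised_phase,
        "adversarial_supervised": _train_pix2pix,
        "cycle_adversarial": _train_cyclegan,
    }
    return dispatch[config.paradigm](config, cohort, ss)


def _supervised_step(gen, cond, patch, cfg, opt, rng):
    if cfg.augment:
        patch = augment_supervised(patch, rng_seed=rng, ranges=cfg.augment_ranges)
    x = Tensor(patch.source_patch[None, None])
    y = Tensor(patch.target_patch[None, None])
    fg = (patch.mask_patch > 0).astype(np.float64)[None, None]
    pred = gen.forward(x, t=patch.phase if cond else None, rng=rng)
    loss = roi_weighted_l1(y, pred, fg, mu=cfg.weights.mu)
    opt.zero_grad()
    loss.backward()
    opt.step()
    return float(loss)


def _train_supervised_phase(cfg, cohort, ss):
    seeds = ss.spawn(2)
    gen = UNetGenerator(_gen_spec(cfg, conditioned=True),
                        seed=int(seeds[0].generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(seeds[1])
    opt = Adam(gen.parameters(), lr=cfg.lr_gen, beta1=cfg.adam_beta1,
               beta2=cfg.adam_beta2)
    cohort_w = [_windowed(c) for c in cohort]
    rows = []
    for step in range(cfg.steps):
        phase = CME if rng.random() < 0.5 else NGE
        patch = _sample_patch(cohort_w, cohort, phase, cfg, rng)
        loss = _supervised_step(gen, True, patch, cfg, opt, rng)
        _check_finite(loss, step, "L_ROI")
        rows.append({"step": step, "phase": phase, "loss_roi": loss})
    return TrainResult({"conditioned": gen}, {}, pd.DataFrame(rows), cfg)


def _train_supervised_baseline(cfg, cohort, ss):
    gens, logs = {}, []
    for k, phase in enumerate((CME, NGE)):
        seeds = ss.spawn(2)
        gen = UNetGenerator(_gen_spec(cfg, conditioned=False),
                            seed=int(seeds[0].generate_state(1)[0] % 2**31))
        rng = np.random.default_rng(seeds[1])
        opt = Adam(gen.parameters(), lr=cfg.lr_gen, beta1=cfg.adam_beta1,
                   beta2=cfg.adam_beta2)
        cohort_w = [_windowed(c) for c in cohort]
        for step in range(cfg.steps):
            patch = _sample_patch(cohort_w, cohort, phase, cfg, rng)
            loss = _supervised_step(gen, False, patch, cfg, opt, rng)
            _check_finite(loss, step, "L_ROI")
            logs.append({"step": step, "phase": phase, "loss_roi": loss})
        gens[phase] = gen
    return TrainResult(gens, {}, pd.DataFrame(logs), cfg)


def _train_pix2pix(cfg, cohort, ss):
    seeds = ss.spawn(3)
    gen = UNetGenerator(_gen_spec(cfg, conditioned=True),
                        seed=int(seeds[0].generate_state(1)[0] % 2**31))
    disc = PatchDiscriminator(_disc_spec(cfg, conditioned=True),
                              seed=int(seeds[1].generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(seeds[2])
    opt_g = Adam(gen.parameters(), lr=cfg.lr_gen, beta1=cfg.adam_beta1,
                 beta2=cfg.adam_beta2)
    opt_d = Adam(disc.parameters(), lr=cfg.lr_disc, beta1=cfg.adam_beta1,
                 beta2=cfg.adam_beta2)
    cohort_w = [_windowed(c) for c in cohort]
    rows = []
    for step in range(cfg.steps):
        phase = CME if rng.random() < 0.5 else NGE
        patch = _sample_patch(cohort_w, cohort, phase, cfg, rng)
        x = Tensor(patch.source_patch[None, None])
        y = Tensor(patch.target_patch[None, None])
        fg = (patch.mask_patch > 0).astype(np.float64)[None, None]
        # discriminator step: one shared augmentation for real and fake
        fake = gen.forward(x, t=phase, rng=rng).detach()
        real_aug, fake_aug = diff_augment([y, fake], rng)
        d_loss = bce_disc_loss(disc.forward(real_aug, t=phase).sigmoid(),
                               disc.forward(fake_aug, t=phase).sigmoid())
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()
        # generator step
        pred = gen.forward(x, t=phase, rng=rng)
        [pred_aug] = diff_augment([pred], rng)
        adv = bce_gen_loss(disc.forward(pred_aug, t=phase).sigmoid())
        l_roi = roi_weighted_l1(y, pred, fg, mu=cfg.weights.mu)
        g_loss = adv + cfg.weights.lam * l_roi
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()
        _check_finite(float(g_loss), step, "L_G")
        _check_finite(float(d_loss), step, "L_D")
        rows.append({"step": step, "phase": phase, "loss_d": float(d_loss),
                     "loss_g": float(g_loss), "loss_adv": float(adv),
                     "loss_roi": float(l_roi)})
    return TrainResult({"conditioned": gen}, {"conditioned": disc},
                       pd.DataFrame(rows), cfg)


def _train_cyclegan(cfg, cohort, ss):
    seeds = ss.spawn(5)
    mk = lambda s: int(s.generate_state(1)[0] % 2**31)
    gen_f = UNetGenerator(_gen_spec(cfg, conditioned=True), seed=mk(seeds[0]))
    gen_b = UNetGenerator(_gen_spec(cfg, conditioned=True), seed=mk(seeds[1]))
    disc_f = PatchDiscriminator(_disc_spec(cfg, conditioned=True), seed=mk(seeds[2]))
    disc_b = PatchDiscriminator(_disc_spec(cfg, conditioned=True), seed=mk(seeds[3]))
    rng = np.random.default_rng(seeds[4])
    opt_g = Adam(gen_f.parameters() + gen_b.parameters(), lr=cfg.lr_gen,
                 beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = Adam(disc_f.parameters() + disc_b.parameters(), lr=cfg.lr_disc,
                 beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    buf_f = ImageBuffer(cfg.buffer_capacity)
    buf_b = ImageBuffer(cfg.buffer_capacity)
    cohort_w = [_windowed(c) for c in cohort]
    lam = cfg.weights.lam
    rows = []
    for step in range(cfg.steps):
        phase = CME if rng.random() < 0.5 else NGE
        # unpaired: source and target patches from different subjects
        p_src = _sample_patch(cohort_w, cohort, phase, cfg, rng)
        p_tgt = _sample_patch(cohort_w, cohort, phase, cfg, rng)
        x = Tensor(p_src.source_patch[None, None])
        y = Tensor(p_tgt.target_patch[None, None])
        # discriminator step with buffered fakes
        fake_y = gen_f.forward(x, t=phase, rng=rng).detach()
        fake_x = gen_b.forward(y, t=phase, rng=rng).detach()
        fy = Tensor(buf_f.sample(fake_y.data, rng))
        fx = Tensor(buf_b.sample(fake_x.data, rng))
        real_y_a, fy_a = diff_augment([y, fy], rng)
        real_x_a, fx_a = diff_augment([x, fx], rng)
        d_loss = (lsgan_disc_loss(disc_f.forward(real_y_a, t=phase),
                                  disc_f.forward(fy_a, t=phase))
                  + lsgan_disc_loss(disc_b.forward(real_x_a, t=phase),
                                    disc_b.forward(fx_a, t=phase)))
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()
        # generator step
        fake_y = gen_f.forward(x, t=phase, rng=rng)
        fake_x = gen_b.forward(y, t=phase, rng=rng)
        [fy_a2] = diff_augment([fake_y], rng)
        [fx_a2] = diff_augment([fake_x], rng)
        adv = (lsgan_gen_loss(disc_f.forward(fy_a2, t=phase))
               + lsgan_gen_loss(disc_b.forward(fx_a2, t=phase)))
        x_rec = gen_b.forward(fake_y, t=phase, rng=rng)
        y_rec = gen_f.forward(fake_x, t=phase, rng=rng)
        l_cyc = cycle_loss(x, x_rec, y, y_rec)
        l_id = identity_loss(x, gen_b.forward(x, t=phase, rng=rng),
                             y, gen_f.forward(y, t=phase, rng=rng))
        g_loss = adv + lam * l_cyc + (lam / 2.0) * l_id
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()
        _check_finite(float(g_loss), step, "L_G")
        _check_finite(float(d_loss), step, "L_D")
        rows.append({"step": step, "phase": phase, "loss_d": float(d_loss),
                     "loss_g": float(g_loss), "loss_adv": float(adv),
                     "loss_cyc": float(l_cyc), "loss_id": float(l_id)})
    return TrainResult({"forward": gen_f, "backward": gen_b},
                       {"forward": disc_f, "backward": disc_b},
                       pd.DataFrame(rows), cfg)


def train_segmentation(images: list[np.ndarray], tumour_masks: list[np.ndarray],
                       lr: float = 1e-3, minibatch: int = 64,
                       epochs: int = 5, first_channels: int = 8,
                       n_layers: int = 3, seed: int = 0):
    """Train the 2D tumour-segmentation U-Net with pixel-wise binary
    cross-entropy; returns (network, per-epoch log DataFrame with mean Dice).
    """
    from .metrics import dice as dice_score

    if len(images) == 0 or len(images) != len(tumour_masks):
        raise ValueError("need equal, non-zero numbers of images and masks")
    ss = np.random.SeedSequence(entropy=seed)
    s_init, s_shuffle = ss.spawn(2)
    net = SegUNet2d(first_channels=first_channels, n_layers=n_layers,
                    seed=int(s_init.generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(s_shuffle)
    opt = Adam(net.core.parameters(), lr=lr, beta1=0.5)
    imgs = np.stack(images).astype(np.float64)[:, None]
    msks = np.stack(tumour_masks).astype(np.float64)[:, None]
    n = len(imgs)
    rows = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, minibatch):
            idx = order[lo:lo + minibatch]
            x = Tensor(imgs[idx])
            y = msks[idx]
            prob = net.forward(x).clip(1e-7, 1 - 1e-7)
            loss = -(Tensor(y) * prob.log()
                     + Tensor(1.0 - y) * (1.0 - prob).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss))
        preds = [net.predict(im[0]) > 0.5 for im in imgs]
        dices = [dice_score(p, m[0]) for p, m in zip(preds, msks)]
        rows.append({"epoch": epoch, "bce": float(np.mean(losses)),
                     "dice": float(np.mean(dices))})
    return net, pd.DataFrame(rows)
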