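"""Training objectives for the three supervision regimes.

All losses are per-voxel means computed in the normalised [0, 1] intensity
space in which the networks operate.  The supervised term splits the mean
absolute error into foreground (aorta + kidney + tumour) and background
parts, mixed by a weight mu; the adversarial pairs come in a binary
cross-entropy flavour (adversarial-with-supervision) and a least-squares
flavour (unpaired cycle training), plus cycle-consistency and identity
terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossWeights", "roi_weighted_l1", "bce_disc_loss", "bce_gen_loss",
    "lsgan_disc_loss", "lsgan_gen_loss", "cycle_loss", "identity_loss",
]

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """mu: foreground weight of the supervised loss; lam: adversarial balance
    (720 for adversarial-with-supervision; 10 for the cycle paradigm, whose
    identity term is weighted lam/2 = 5)."""
    mu: float = 0.2
    lam: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_shapes(*arrays):
    shapes = {tuple(_wrap(a).shape) for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def roi_weighted_l1(target, prediction, fg_mask, mu: float = 0.2) -> Tensor:
    """mu * mean|err| over foreground + (1 - mu) * mean|err| over background.

    An empty region contributes 0.  Equals the plain mean absolute error only
    when both region means coincide.
    """
    target, prediction = _wrap(target), _wrap(prediction)
    fg = np.asarray(fg_mask, dtype=np.float64)
    _check_shapes(target, prediction)
    if fg.shape != tuple(target.shape):
        raise ValueError("fg_mask shape mismatch")
    err = (target - prediction).abs()
    n_fg = fg.sum()
    n_bg = fg.size - n_fg
    total = _wrap(0.0)
    if n_fg > 0:
        total = total + mu * ((err * Tensor(fg)).sum() * (1.0 / n_fg))
    if n_bg > 0:
        total = total + (1.0 - mu) * ((err * Tensor(1.0 - fg)).sum() * (1.0 / n_bg))
    return total


def bce_disc_loss(real_scores, fake_scores) -> Tensor:
    """-mean ln(real) - mean ln(1 - fake); scores are probabilities."""
    real = _wrap(real_scores).clip(EPS, 1.0 - EPS)
    fake = _wrap(fake_scores).clip(EPS, 1.0 - EPS)
    return -(real.log().mean()) - ((1.0 - fake).log().mean())


def bce_gen_loss(fake_scores) -> Tensor:
    """-mean ln(fake): the generator wants the discriminator fooled."""
    fake = _wrap(fake_scores).clip(EPS, 1.0 - EPS)
    return -(fake.log().mean())


def lsgan_disc_loss(real_scores, fake_scores) -> Tensor:
    """mean (real - 1)^2 + mean fake^2 (least-squares convention)."""
    real, fake = _wrap(real_scores), _wrap(fake_scores)
    if not (np.isfinite(real.data).all() and np.isfinite(fake.data).all()):
        raise ValueError("non-finite discriminator scores")
    return ((real - 1.0) ** 2.0).mean() + (fake ** 2.0).mean()


def lsgan_gen_loss(fake_scores) -> Tensor:
    fake = _wrap(fake_scores)
    if not np.isfinite(fake.data).all():
        raise ValueError("non-finite discriminator scores")
    return ((fake - 1.0) ** 2.0).mean()


def cycle_loss(x, x_reconstructed, y, y_reconstructed) -> Tensor:
    """mean|x - f_inv(f(x))| + mean|y - f(f_inv(y))|."""
    x, xr, y, yr = map(_wrap, (x, x_reconstructed, y, y_reconstructed))
    _check_shapes(x, xr)
    _check_shapes(y, yr)
    return (x - xr).abs().mean() + (y - yr).abs().mean()


def identity_loss(x, f_inv_of_x, y, f_of_y) -> Tensor:
    """mean|x - f_inv(x)| + mean|y - f(y)|: each generator should leave an
    image from its own target domain unchanged."""
    return cycle_loss(x, f_inv_of_x, y, f_of_y)
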