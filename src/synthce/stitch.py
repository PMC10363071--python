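"""Full-volume inference: sliding-window prediction with overlap averaging.

The generator sees fixed-size cubic patches, so a whole volume is predicted
by running it at every window position on a regular stride grid and
averaging all predictions covering each voxel.  The last window on each axis
is placed flush with the boundary, so every voxel is covered at least once
and no synthetic padding enters the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctdata import WindowedVolume, denormalise, window_normalise

__all__ = ["StitchConfig", "axis_origins", "stitch_predict", "predict_hu"]


@dataclass(frozen=True)
class StitchConfig:
    patch_size: int = 64
    stride: int = 16
    phase: int | None = None
    dropout_seed: int = 0

    def __post_init__(self):
        if not 1 <= self.stride <= self.patch_size:
            raise ValueError("stride must satisfy 1 <= stride <= patch_size")


def axis_origins(dim: int, patch_size: int, stride: int) -> list[int]:
    """Window origins along one axis: the stride grid plus a final origin
    clamped flush with the boundary."""
    if patch_size > dim:
        raise ValueError("volume smaller than patch")
    origins = list(range(0, dim - patch_size + 1, stride))
    last = dim - patch_size
    if origins[-1] != last:
        origins.append(last)
    return origins


def stitch_predict(generator, volume: WindowedVolume,
                   cfg: StitchConfig) -> WindowedVolume:
    """Average the generator's output over all overlapping windows.

    ``generator`` is any callable mapping a (ps, ps, ps) array in [0, 1] to a
    same-shaped array; network objects are adapted via their ``predict``
    method, with the phase label and a fixed dropout seed taken from ``cfg``
    so runs are reproducible.
    """
    fn = _as_patch_fn(generator, cfg)
    data = volume.data
    ps = cfg.patch_size
    origins = [axis_origins(d, ps, cfg.stride) for d in data.shape]
    acc = np.zeros_like(data)
    count = np.zeros_like(data)
    for o0 in origins[0]:
        for o1 in origins[1]:
            for o2 in origins[2]:
                sl = (slice(o0, o0 + ps), slice(o1, o1 + ps),
                      slice(o2, o2 + ps))
                acc[sl] += fn(data[sl])
                count[sl] += 1.0
    return WindowedVolume(acc / count, volume.window_low, volume.window_high,
                          provenance=volume.provenance + "|stitched")


def _as_patch_fn(generator, cfg: StitchConfig):
    if callable(generator) and not hasattr(generator, "predict"):
        return generator
    # network object: bind the phase and a fresh, fixed-seed dropout stream
    rng = np.random.default_rng(cfg.dropout_seed)
    if getattr(generator, "spec", None) is not None and generator.spec.conditioned:
        if cfg.phase is None:
            raise ValueError("conditioned generator requires cfg.phase")
        return lambda patch: generator.predict(patch, t=cfg.phase, rng=rng)
    return lambda patch: generator.predict(patch, rng=rng)


def predict_hu(generator, nce_volume_hu: np.ndarray, cfg: StitchConfig,
               window_low: float = -500.0,
               window_high: float = 2500.0) -> np.ndarray:
    """window -> sliding-window prediction -> back to Hounsfield units."""
    wv = window_normalise(nce_volume_hu, window_low, window_high)
    return denormalise(stitch_predict(generator, wv, cfg))
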