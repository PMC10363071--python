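"""Phase-conditioned translation networks.

A single generator produces either contrast phase from a non-contrast input
by tiling the scalar phase label (1 = corticomedullary, 2 = nephrogenic) as
an extra constant channel concatenated to each decoder layer's input.  The
discriminator is a 3D patch discriminator (PatchGAN): it scores overlapping
receptive fields rather than whole images, and is conditioned by tiling the
phase onto its input.  A small 2D U-Net supports the downstream tumour
segmentation task.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (ConvNd, ConvTransposeNd, InstanceNorm, Module, Tensor,
                 concat, dropout)

__all__ = [
    "PhaseLabel", "GeneratorSpec", "DiscriminatorSpec", "tile_phase",
    "UNetGenerator", "PatchDiscriminator", "SegUNet2d",
    "build_generator", "build_discriminator", "build_seg_unet_2d",
    "save_checkpoint", "load_checkpoint",
]

VALID_PHASES = (1, 2)


@dataclass(frozen=True)
class PhaseLabel:
    """Contrast phase: 1 = corticomedullary (CME), 2 = nephrogenic (NGE)."""
    value: int

    def __post_init__(self):
        if self.value not in VALID_PHASES:
            raise ValueError(f"phase must be in {VALID_PHASES}")


def _phase_value(t) -> int:
    v = t.value if isinstance(t, PhaseLabel) else int(t)
    if v not in VALID_PHASES:
        raise ValueError(f"phase must be in {VALID_PHASES}")
    return v


@dataclass(frozen=True)
class GeneratorSpec:
    n_layers: int = 5
    first_channels: int = 32
    conditioned: bool = False
    dropout_decoder_layers: int = 0
    norm: bool = True
    nd: int = 3

    def __post_init__(self):
        if self.n_layers < 2 or self.first_channels < 1:
            raise ValueError("n_layers >= 2 and first_channels >= 1 required")


@dataclass(frozen=True)
class DiscriminatorSpec:
    n_layers: int = 3
    first_channels: int = 16
    conditioned: bool = False
    nd: int = 3

    def __post_init__(self):
        if self.n_layers < 1 or self.first_channels < 1:
            raise ValueError("n_layers >= 1 and first_channels >= 1 required")


def tile_phase(features, t) -> Tensor:
    """Append one constant channel carrying the raw phase value (1 or 2).

    ``features`` is (C, *spatial) or (N, C, *spatial); existing channels are
    untouched.
    """
    v = _phase_value(t)
    x = features if isinstance(features, Tensor) else Tensor(features)
    if x.ndim == 4:  # (C, D, H, W) — single 3D sample
        ch_axis = 0
    else:
        ch_axis = 1
    shape = list(x.shape)
    shape[ch_axis] = 1
    plane = Tensor(np.full(shape, float(v)))
    return concat([x, plane], axis=ch_axis)


class UNetGenerator(Module):
    """Encoder-decoder with skip connections.

    Down blocks: strided convolution (k3, s2) + instance norm + leaky ReLU
    (no norm on the first layer).  Up blocks: transpose convolution (k4, s2),
    concatenation with the matching encoder feature map, then a plain
    convolution.  The phase channel is tiled onto every decoder block's input
    (never the output layer); 50% dropout noise in the first
    ``dropout_decoder_layers`` decoder blocks stays active at inference.
    Output passes through a sigmoid so predictions respect the [0, 1]
    windowed-intensity range.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        nd, L, F = spec.nd, spec.n_layers, spec.first_channels
        cond = 1 if spec.conditioned else 0
        ch = [F * 2 ** i for i in range(L)]
        self.enc = []
        in_ch = 1
        for i in range(L):
            self.enc.append(ConvNd(in_ch, ch[i], 3, nd=nd, stride=2, rng=rng))
            in_ch = ch[i]
        self.enc_norm = [InstanceNorm(ch[i], nd=nd) if (spec.norm and i > 0)
                         else None for i in range(L)]
        self.up = []
        self.up_norm = []
        self.post = []
        self.post_norm = []
        cur = ch[-1]
        for j in range(L):
            out_ch = ch[L - 2 - j] if j < L - 1 else F
            self.up.append(ConvTransposeNd(cur + cond, out_ch, 4, nd=nd, rng=rng))
            self.up_norm.append(InstanceNorm(out_ch, nd=nd) if spec.norm else None)
            if j < L - 1:
                self.post.append(ConvNd(out_ch * 2, out_ch, 3, nd=nd, rng=rng))
                self.post_norm.append(
                    InstanceNorm(out_ch, nd=nd) if spec.norm else None)
            else:
                self.post.append(None)
                self.post_norm.append(None)
            cur = out_ch
        self.out_conv = ConvNd(F, 1, 3, nd=nd, rng=rng)

    def forward(self, x: Tensor, t=None,
                rng: np.random.Generator | None = None) -> Tensor:
        spec = self.spec
        if spec.conditioned and t is None:
            raise ValueError("conditioned generator requires a phase label")
        if not spec.conditioned and t is not None:
            raise ValueError("unconditioned generator accepts no phase label")
        if spec.dropout_decoder_layers > 0 and rng is None:
            rng = np.random.default_rng(0)
        skips = []
        h = x
        for i, enc in enumerate(self.enc):
            h = enc(h)
            if self.enc_norm[i] is not None:
                h = self.enc_norm[i](h)
            h = h.leaky_relu(0.2)
            skips.append(h)
        for j in range(spec.n_layers):
            if spec.conditioned:
                h = tile_phase(h, t)
            h = self.up[j](h)
            if self.up_norm[j] is not None:
                h = self.up_norm[j](h)
            h = h.relu()
            if self.post[j] is not None:
                h = concat([h, skips[spec.n_layers - 2 - j]], axis=1)
                h = self.post[j](h)
                if self.post_norm[j] is not None:
                    h = self.post_norm[j](h)
                h = h.relu()
            if j < spec.dropout_decoder_layers:
                h = dropout(h, 0.5, rng)
        return self.out_conv(h).sigmoid()

    def predict(self, volume: np.ndarray, t=None, seed: int = 0,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Numpy convenience wrapper: (D, H, W) in [0, 1] -> same shape."""
        if rng is None:
            rng = np.random.default_rng(seed)
        x = Tensor(np.asarray(volume)[None, None])
        return self.forward(x, t=t, rng=rng).data[0, 0]


class PatchDiscriminator(Module):
    """PatchGAN: stacked strided convolutions to a spatial map of raw
    real/fake scores; phase conditioning tiles the label onto the input."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        nd, L, F = spec.nd, spec.n_layers, spec.first_channels
        in_ch = 1 + (1 if spec.conditioned else 0)
        self.convs = []
        self.norms = []
        ch = in_ch
        for i in range(L):
            out_ch = F * 2 ** i
            self.convs.append(ConvNd(ch, out_ch, 4, nd=nd, stride=2,
                                     padding=1, rng=rng))
            self.norms.append(InstanceNorm(out_ch, nd=nd) if i > 0 else None)
            ch = out_ch
        self.out_conv = ConvNd(ch, 1, 4, nd=nd, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor, t=None) -> Tensor:
        if self.spec.conditioned and t is None:
            raise ValueError("conditioned discriminator requires a phase label")
        if not self.spec.conditioned and t is not None:
            raise ValueError("unconditioned discriminator accepts no phase label")
        h = tile_phase(x, t) if self.spec.conditioned else x
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
        return self.out_conv(h)

    def predict(self, volume: np.ndarray, t=None) -> np.ndarray:
        return self.forward(Tensor(np.asarray(volume)[None, None]), t=t).data[0, 0]


class SegUNet2d(Module):
    """2D U-Net emitting per-pixel tumour probabilities on 64x64 patches."""

    def __init__(self, first_channels: int = 16, n_layers: int = 3,
                 seed: int = 0):
        self.core = UNetGenerator(
            GeneratorSpec(n_layers=n_layers, first_channels=first_channels,
                          conditioned=False, nd=2), seed=seed)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError("expected (N, 1, H, W) input")
        div = 2 ** self.core.spec.n_layers
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims must be divisible by {div}")
        return self.core.forward(x)

    def predict(self, image: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.asarray(image)[None, None])).data[0, 0]


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed=seed)


def build_seg_unet_2d(first_channels: int = 16, n_layers: int = 3,
                      seed: int = 0) -> SegUNet2d:
    return SegUNet2d(first_channels, n_layers, seed=seed)


def save_checkpoint(model: Module, path_prefix: str | Path):
    """Write weights (.npz) plus a JSON sidecar describing the architecture,
    so checkpoints are self-describing."""
    path_prefix = Path(path_prefix)
    path_prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(path_prefix) + ".npz", **dict(model.state_dict()))
    if isinstance(model, UNetGenerator):
        meta = {"kind": "generator", "spec": asdict(model.spec)}
    elif isinstance(model, PatchDiscriminator):
        meta = {"kind": "discriminator", "spec": asdict(model.spec)}
    elif isinstance(model, SegUNet2d):
        meta = {"kind": "seg_unet_2d",
                "spec": {"first_channels": model.core.spec.first_channels,
                         "n_layers": model.core.spec.n_layers}}
    else:
        raise TypeError(f"unknown model type {type(model)}")
    Path(str(path_prefix) + ".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path_prefix: str | Path) -> Module:
    path_prefix = Path(path_prefix)
    meta = json.loads(Path(str(path_prefix) + ".json").read_text())
    if meta["kind"] == "generator":
        model = UNetGenerator(GeneratorSpec(**meta["spec"]))
    elif meta["kind"] == "discriminator":
        model = PatchDiscriminator(DiscriminatorSpec(**meta["spec"]))
    elif meta["kind"] == "seg_unet_2d":
        model = SegUNet2d(**meta["spec"])
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']}")
    with np.load(str(path_prefix) + ".npz") as data:
        model.load_state_dict(dict(data))
    return model
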