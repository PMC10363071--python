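"""CT intensity windowing, patch extraction and paired affine augmentation.

Intensities are windowed to a Hounsfield range (default [-500, 2500], wide
enough to keep metal-density features) and mapped affinely to [0, 1]; the
mapping is invertible, so network outputs convert back to HU for evaluation.
Training uses 3D patches cut identically from source volume, target volume
and ROI mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "WindowedVolume", "PatchSample", "window_normalise", "denormalise",
    "extract_patches", "AugmentRanges", "AffineParams", "augment_supervised",
    "load_nifti", "save_nifti", "downsample_inplane",
]

WINDOW_LOW = -500.0
WINDOW_HIGH = 2500.0


@dataclass
class WindowedVolume:
    data: np.ndarray
    window_low: float = WINDOW_LOW
    window_high: float = WINDOW_HIGH
    provenance: str = ""

    def __post_init__(self):
        if self.window_high <= self.window_low:
            raise ValueError("window_high must exceed window_low")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class PatchSample:
    source_patch: np.ndarray
    target_patch: np.ndarray
    mask_patch: np.ndarray
    origin: tuple[int, int, int]
    phase: int = 1


def window_normalise(volume_hu: np.ndarray, low: float = WINDOW_LOW,
                     high: float = WINDOW_HIGH,
                     provenance: str = "") -> WindowedVolume:
    """Clip to [low, high] HU and rescale to [0, 1]."""
    if high <= low:
        raise ValueError("high must exceed low")
    volume_hu = np.asarray(volume_hu, dtype=np.float64)
    if not np.isfinite(volume_hu).all():
        raise ValueError("volume contains non-finite voxels")
    data = (np.clip(volume_hu, low, high) - low) / (high - low)
    return WindowedVolume(data, low, high, provenance)


def denormalise(wv: WindowedVolume) -> np.ndarray:
    """Invert the windowing map on [0, 1] back to HU."""
    return wv.data * (wv.window_high - wv.window_low) + wv.window_low


def extract_patches(source: WindowedVolume, target: WindowedVolume,
                    mask: np.ndarray, n: int, patch_size: int,
                    rng_seed: int | np.random.Generator = 0,
                    phase: int = 1,
                    foreground_bias: float = 0.5,
                    max_attempts: int = 200) -> list[PatchSample]:
    """Sample ``n`` aligned cubic patches.

    With probability ``foreground_bias`` a patch is rejection-resampled until
    it contains at least one labelled voxel (mostly-background volumes
    otherwise dominate training); otherwise the origin is uniform over valid
    corners.
    """
    if source.data.shape != target.data.shape or source.data.shape != mask.shape:
        raise ValueError("source, target and mask must share one shape")
    shape = source.data.shape
    if any(patch_size > s for s in shape):
        raise ValueError("patch_size exceeds a volume dimension")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    hi = [s - patch_size for s in shape]
    out = []
    for _ in range(n):
        want_fg = rng.random() < foreground_bias
        for _ in range(max_attempts):
            origin = tuple(int(rng.integers(0, h + 1)) for h in hi)
            sl = tuple(slice(o, o + patch_size) for o in origin)
            if not want_fg or (mask[sl] > 0).any():
                break
        out.append(PatchSample(
            source_patch=source.data[sl].copy(),
            target_patch=target.data[sl].copy(),
            mask_patch=mask[sl].copy(),
            origin=origin, phase=phase,
        ))
    return out


@dataclass(frozen=True)
class AugmentRanges:
    """Parameter ranges for the supervised-path affine augmentation; modest
    defaults preserve gross anatomy."""
    rotate_deg: float = 15.0
    scale: tuple[float, float] = (0.9, 1.1)
    shear_deg: float = 5.0
    translate_vox: float = 8.0
    flip_prob: float = 0.5


@dataclass(frozen=True)
class AffineParams:
    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shear_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    flips: tuple[bool, bool, bool] = (False, False, False)

    @classmethod
    def draw(cls, rng: np.random.Generator,
             ranges: AugmentRanges = AugmentRanges()) -> "AffineParams":
        return cls(
            angles_deg=tuple(rng.uniform(-ranges.rotate_deg, ranges.rotate_deg)
                             for _ in range(3)),
            scales=tuple(rng.uniform(*ranges.scale) for _ in range(3)),
            shear_deg=float(rng.uniform(-ranges.shear_deg, ranges.shear_deg)),
            translation=tuple(rng.uniform(-ranges.translate_vox,
                                          ranges.translate_vox)
                              for _ in range(3)),
            flips=tuple(bool(rng.random() < ranges.flip_prob)
                        for _ in range(3)),
        )

    def matrix(self) -> np.ndarray:
        a, b, c = np.deg2rad(self.angles_deg)
        rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)],
                       [0, np.sin(a), np.cos(a)]])
        ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0],
                       [-np.sin(b), 0, np.cos(b)]])
        rz = np.array([[np.cos(c), -np.sin(c), 0],
                       [np.sin(c), np.cos(c), 0], [0, 0, 1]])
        sh = np.eye(3)
        sh[1, 2] = np.tan(np.deg2rad(self.shear_deg))
        m = rx @ ry @ rz @ sh @ np.diag(self.scales)
        m = m @ np.diag([-1.0 if f else 1.0 for f in self.flips])
        return m


def _apply_affine(vol: np.ndarray, params: AffineParams,
                  order: int) -> np.ndarray:
    m = params.matrix()
    centre = (np.asarray(vol.shape) - 1) / 2.0
    # output coordinate y maps to input coordinate m @ (y - centre) + centre - t
    offset = centre - m @ centre - np.asarray(params.translation)
    # edge-value fill: constant fill would paint window-floor (air-density)
    # wedges into every rotated patch, which distorts small patches badly
    return ndimage.affine_transform(vol, m, offset=offset, order=order,
                                    mode="nearest")


def augment_supervised(sample: PatchSample,
                       rng_seed: int | np.random.Generator = 0,
                       ranges: AugmentRanges = AugmentRanges(),
                       params: AffineParams | None = None) -> PatchSample:
    """Apply one random affine identically to source, target and mask.

    The mask is resampled nearest-neighbour; image intensities trilinear and
    clipped back to [0, 1].  Passing ``params`` forces a specific transform.
    """
    if params is None:
        rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
               else np.random.default_rng(rng_seed))
        params = AffineParams.draw(rng, ranges)
    src = np.clip(_apply_affine(sample.source_patch, params, 1), 0.0, 1.0)
    tgt = np.clip(_apply_affine(sample.target_patch, params, 1), 0.0, 1.0)
    msk = _apply_affine(sample.mask_patch.astype(np.float64), params, 0)
    return PatchSample(src, tgt, msk.astype(sample.mask_patch.dtype),
                       sample.origin, sample.phase)


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (volume, affine) with the volume as float64."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def save_nifti(volume: np.ndarray, path: str | Path,
               affine: np.ndarray | None = None):
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))


def downsample_inplane(volume: np.ndarray, target: int = 256,
                       order: int = 1) -> np.ndarray:
    """Resample each axial slice to target x target (depth untouched)."""
    factors = (1.0, target / volume.shape[1], target / volume.shape[2])
    return ndimage.zoom(volume, factors, order=order)
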