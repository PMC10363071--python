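"""Image-quality metrics in Hounsfield space, ROI intensity sampling, Dice.

pSNR uses a peak of 65535 (16-bit maximum) and SSIM the same data range;
with these conventions 10*log10(peak^2 / MSE) is self-consistent across the
MSE/pSNR pairs reported for this kind of CT translation task.  SSIM is the
standard locally-windowed form (K1 = 0.01, K2 = 0.03) computed over a 3D
sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["RoiSample", "mse", "psnr", "ssim", "sample_roi", "dice",
           "PEAK_16BIT"]

PEAK_16BIT = 65535.0


def _check(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    a, b = _check(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a=None, b=None, peak: float = PEAK_16BIT, *,
         mse_value: float | None = None) -> float:
    """10*log10(peak^2 / MSE); returns +inf for identical inputs.

    Either two volumes or a precomputed ``mse_value`` may be given.
    """
    if mse_value is None:
        mse_value = mse(a, b)
    if mse_value == 0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / mse_value))


def ssim(a, b, data_range: float = PEAK_16BIT, win_size: int = 7,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity over a uniform N-d sliding window.

    Matches the classic Wang et al. formulation with uniform (not Gaussian)
    weighting and sample (ddof=1) covariance normalisation.
    """
    a, b = _check(a, b)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    n = win_size ** a.ndim
    cov_norm = n / (n - 1)

    def f(x):
        return uniform_filter(x, size=win_size)

    ua, ub = f(a), f(b)
    uaa, ubb, uab = f(a * a), f(b * b), f(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / (
        (ua ** 2 + ub ** 2 + c1) * (va + vb + c2))
    # crop the filter's edge effects, as reference implementations do
    pad = (win_size - 1) // 2
    interior = tuple(slice(pad, dim - pad) for dim in s.shape)
    return float(s[interior].mean())


@dataclass
class RoiSample:
    roi: str
    phase: int
    subject_id: str
    voxel_values: np.ndarray

    @property
    def mean_hu(self) -> float:
        return float(np.mean(self.voxel_values))


def sample_roi(mask: np.ndarray, volume_hu: np.ndarray, roi: str,
               n_slices: int = 5, subject_id: str = "",
               phase: int = 1) -> RoiSample | None:
    """Collect ROI voxel intensities the way the evaluation protocol samples
    them: for aorta/cortex/medulla, all ROI voxels on ``n_slices`` equally
    spaced axial slices spanning the ROI's slice range (inclusive endpoints,
    rounded, duplicates collapsed); for tumour, every ROI voxel.

    Returns None when a tumour is absent (such subjects are omitted);
    raises for any other absent ROI.
    """
    from .phantom import ROI_LABELS

    if roi not in ROI_LABELS:
        raise ValueError(f"unknown roi {roi!r}")
    lab = ROI_LABELS[roi]
    sel = mask == lab
    if not sel.any():
        if roi == "tumour":
            return None
        raise ValueError(f"roi {roi!r} absent from mask")
    if roi == "tumour":
        values = volume_hu[sel]
    else:
        present = np.where(sel.any(axis=(1, 2)))[0]
        lo, hi = present[0], present[-1]
        slices = np.unique(np.round(np.linspace(lo, hi, n_slices)).astype(int))
        picked = np.zeros_like(sel)
        picked[slices] = sel[slices]
        values = volume_hu[picked]
    return RoiSample(roi=roi, phase=phase, subject_id=subject_id,
                     voxel_values=np.asarray(values, dtype=np.float64))


def dice(pred_mask, true_mask) -> float:
    """2|A n B| / (|A| + |B|); defined as 1.0 when both masks are empty."""
    a, b = _check(pred_mask, true_mask)
    a = a > 0.5
    b = b > 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
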