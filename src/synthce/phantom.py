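"""Synthetic multi-phase abdominal CT phantoms with known enhancement.

Each subject is a triple of aligned Hounsfield-unit volumes — non-contrast
(NCE), corticomedullary phase (CME, ~35 s post-injection) and nephrogenic
phase (NGE, ~80 s) — plus an integer region-of-interest label map.  Contrast
uptake is simulated as a per-subject additive Hounsfield uplift on each ROI,
drawn from a truncated normal so the cohort reproduces the clinically
observed inter-subject variability of enhancement: CME strongly enhances the
aorta and renal cortex, NGE enhances the kidney more uniformly, and tumours
enhance weakly in both phases.

Geometry is deliberately simple (tube, ellipsoids, sphere): the translation
networks only need contrast structure, not anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CME", "NGE", "ROI_LABELS", "PhantomSpec", "SubjectCase",
    "generate_cohort", "generate_interventional_case", "save_cohort",
]

CME = 1
NGE = 2
PHASES = (CME, NGE)
PHASE_NAMES = {CME: "cme", NGE: "nge"}

ROI_LABELS = {"aorta": 1, "cortex": 2, "medulla": 3, "tumour": 4}
ROI_NAMES = {v: k for k, v in ROI_LABELS.items()}

# Mean additive enhancement (HU) per (ROI, phase); inter-subject SD defaults
# to 20% of the mean, which reproduces ground-truth intensity ranges wider
# than those of a consistent predictor.
DEFAULT_UPLIFT_MEAN = {
    ("aorta", CME): 250.0, ("cortex", CME): 120.0,
    ("medulla", CME): 40.0, ("tumour", CME): 30.0,
    ("aorta", NGE): 100.0, ("cortex", NGE): 100.0,
    ("medulla", NGE): 90.0, ("tumour", NGE): 40.0,
}

# Per-ROI geometry sampling ranges, in units of the grid edge (so the phantom
# scales with grid_size).  Kidney/medulla/tumour radii; aorta tube radius.
DEFAULT_ROI_GEOMETRY = {
    "aorta_radius": (0.05, 0.07),
    "kidney_radii": (0.10, 0.16),
    "medulla_scale": (0.5, 0.65),   # medulla ellipsoid relative to kidney
    "tumour_radius": (0.055, 0.09),
}

# Pre-contrast (NCE) mean HU per tissue.  The abdominal background mixes fat
# and soft tissue, so organs are visibly denser on NCE (as in real CT, where
# perirenal fat delineates the kidney); blood pool slightly above parenchyma.
BASE_HU = {"background": -30.0, "aorta": 50.0, "cortex": 35.0,
           "medulla": 25.0, "tumour": 45.0}


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 64
    voxel_spacing_mm: float = 3.0
    n_subjects: int = 10
    seed: int = 0
    tissue_base_hu: tuple[float, float] = (-30.0, 10.0)  # mean, SD of texture
    roi_geometry: dict = field(default_factory=lambda: dict(DEFAULT_ROI_GEOMETRY))
    uplift_mean: dict = field(default_factory=lambda: dict(DEFAULT_UPLIFT_MEAN))
    uplift_sd: dict | None = None   # None -> 20% of the mean
    noise_sd_hu: float = 15.0
    interventional: bool = False
    window_ceiling_hu: float = 2500.0

    def __post_init__(self):
        if self.grid_size < 32:
            raise ValueError("grid_size must be >= 32")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd_hu < 0 or self.tissue_base_hu[1] < 0:
            raise ValueError("standard deviations must be >= 0")
        for k, v in self.uplift_mean.items():
            if not np.isfinite(v):
                raise ValueError(f"uplift_mean[{k}] must be finite")
        if self.uplift_sd is not None and any(v < 0 for v in self.uplift_sd.values()):
            raise ValueError("uplift SDs must be >= 0")

    def sd_for(self, roi: str, phase: int) -> float:
        if self.uplift_sd is not None:
            return self.uplift_sd[(roi, phase)]
        return 0.2 * abs(self.uplift_mean[(roi, phase)])


@dataclass
class SubjectCase:
    subject_id: str
    nce: np.ndarray
    cme: np.ndarray
    nge: np.ndarray
    roi_mask: np.ndarray
    true_uplift: dict

    def volume(self, phase: int | None) -> np.ndarray:
        if phase is None:
            return self.nce
        return {CME: self.cme, NGE: self.nge}[phase]


class GeometryError(RuntimeError):
    """Raised when no valid ROI layout could be sampled."""


def _ellipsoid_mask(shape, centre, radii):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, centre, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _sample_geometry(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Paint the label map: tube aorta, two kidneys (cortex shell around a
    medullary core), one tumour sphere abutting the left kidney.  Later labels
    overwrite earlier ones so every voxel carries exactly one label."""
    n = spec.grid_size
    geo = spec.roi_geometry
    mask = np.zeros((n, n, n), dtype=np.int16)

    def u(lo_hi):
        return rng.uniform(*lo_hi)

    # aorta: vertical tube through the full slice stack, near volume centre
    ar = u(geo["aorta_radius"]) * n
    ac = (n / 2 + rng.uniform(-0.03, 0.03) * n,
          n / 2 + rng.uniform(-0.05, 0.05) * n)
    rr, cc = np.ogrid[0:n, 0:n]
    tube = ((rr - ac[0]) ** 2 + (cc - ac[1]) ** 2) <= ar ** 2
    mask[:, tube] = ROI_LABELS["aorta"]

    # kidneys: ellipsoids flanking the aorta
    kidney_centres = []
    for side in (-1, 1):
        radii = np.array([u(geo["kidney_radii"]) * n for _ in range(3)])
        radii[0] *= 1.3   # elongated along the slice axis
        centre = np.array([
            n / 2 + rng.uniform(-0.05, 0.05) * n,
            n / 2 + rng.uniform(-0.02, 0.02) * n,
            n / 2 + side * (0.28 + rng.uniform(0, 0.04)) * n,
        ])
        kidney = _ellipsoid_mask(mask.shape, centre, radii)
        mask[kidney & (mask == 0)] = ROI_LABELS["cortex"]
        med = _ellipsoid_mask(mask.shape, centre, radii * u(geo["medulla_scale"]))
        mask[med & (mask == ROI_LABELS["cortex"])] = ROI_LABELS["medulla"]
        kidney_centres.append((centre, radii))

    # tumour: sphere abutting the left kidney's lateral surface
    centre, radii = kidney_centres[0]
    tr = u(geo["tumour_radius"]) * n
    tc = centre + np.array([0.0, 0.0, -(radii[2] * 0.8)])
    tum = _ellipsoid_mask(mask.shape, tc, (tr, tr, tr))
    mask[tum] = ROI_LABELS["tumour"]
    return mask


def _realise_uplifts(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw one additive enhancement per (ROI, phase), truncated at zero for
    enhancing ROIs (contrast cannot darken tissue)."""
    uplift = {}
    for (roi, phase), mu in spec.uplift_mean.items():
        sd = spec.sd_for(roi, phase)
        val = rng.normal(mu, sd) if sd > 0 else mu
        if mu > 0:
            val = max(val, 0.0)
        uplift[(roi, phase)] = float(val)
    return uplift


def _base_volume(spec: PhantomSpec, mask: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    base = np.full(mask.shape, BASE_HU["background"], dtype=np.float64)
    for roi, lab in ROI_LABELS.items():
        base[mask == lab] = BASE_HU[roi]
    texture_sd = spec.tissue_base_hu[1]
    base += spec.tissue_base_hu[0] - BASE_HU["background"]
    if texture_sd > 0:
        base += rng.normal(0.0, texture_sd, size=mask.shape)
    return base


def generate_cohort(spec: PhantomSpec, max_retries: int = 20) -> list[SubjectCase]:
    """Generate ``spec.n_subjects`` phantom subjects.

    Identical spec + seed gives a bit-identical cohort.  Geometry is resampled
    (up to ``max_retries`` times) if any ROI would occupy zero voxels.
    """
    root = np.random.SeedSequence(entropy=spec.seed)
    cases = []
    for i, child in enumerate(root.spawn(spec.n_subjects)):
        rng = np.random.default_rng(child)
        for attempt in range(max_retries):
            mask = _sample_geometry(spec, rng)
            counts = [(mask == lab).sum() for lab in ROI_LABELS.values()]
            if all(c > 0 for c in counts):
                break
        else:
            raise GeometryError(
                f"subject {i}: could not sample non-degenerate ROI geometry "
                f"in {max_retries} attempts")
        uplift = _realise_uplifts(spec, rng)
        base = _base_volume(spec, mask, rng)
        volumes = {}
        for phase in (None, CME, NGE):
            vol = base.copy()
            if phase is not None:
                for roi, lab in ROI_LABELS.items():
                    vol[mask == lab] += uplift[(roi, phase)]
            if spec.noise_sd_hu > 0:
                vol += rng.normal(0.0, spec.noise_sd_hu, size=vol.shape)
            volumes[phase] = vol
        cases.append(SubjectCase(
            subject_id=f"subj{i:03d}",
            nce=volumes[None], cme=volumes[CME], nge=volumes[NGE],
            roi_mask=mask, true_uplift=uplift,
        ))
    return cases


def generate_interventional_case(spec: PhantomSpec, base: SubjectCase,
                                 streak_amplitude_hu: float = 60.0,
                                 rod_radius_vox: float = 1.2,
                                 seed: int = 0) -> SubjectCase:
    """Intra-procedural variant: a metal-density needle (clipped at the HU
    window ceiling) advanced toward the tumour, with radial streak artefacts
    around its shaft.  ROI labels are untouched."""
    if not spec.interventional:
        raise ValueError("spec.interventional must be enabled")
    rng = np.random.default_rng(seed)
    nce = base.nce.copy()
    shape = nce.shape
    tum = np.argwhere(base.roi_mask == ROI_LABELS["tumour"])
    if tum.size == 0:
        raise GeometryError("no tumour to target")
    target = tum.mean(axis=0)
    # entry point on the lateral face, same slice as the tumour centre
    entry = np.array([target[0], target[1], 0.0])
    if not (0 <= target[0] < shape[0]):
        raise GeometryError("rod path outside volume")
    n_steps = int(np.linalg.norm(target - entry) * 2) + 1
    path = entry[None, :] + np.linspace(0, 1, n_steps)[:, None] * (target - entry)
    zz, yy = np.ogrid[0:shape[1], 0:shape[2]]
    rod = np.zeros(shape, dtype=bool)
    for p in path:
        s = int(round(p[0]))
        if not (0 <= s < shape[0]):
            raise GeometryError("rod path outside volume")
        disc = ((yy - p[2]) ** 2 + (zz - p[1]) ** 2) <= rod_radius_vox ** 2
        rod[s][disc] = True
    nce[rod] = spec.window_ceiling_hu
    if streak_amplitude_hu > 0:
        # sinusoidal bright/dark streaks radiating from the shaft, fading with
        # distance (photon-starvation-like pattern)
        mid = path[n_steps // 2]
        ang = np.arctan2(zz - mid[1], yy - mid[2])
        dist = np.sqrt((yy - mid[2]) ** 2 + (zz - mid[1]) ** 2)
        pattern = (streak_amplitude_hu * np.sin(8 * ang + rng.uniform(0, 2 * np.pi))
                   * np.exp(-dist / (0.25 * shape[1])))
        slices = sorted({int(round(p[0])) for p in path})
        for s in slices:
            nce[s] += np.where(rod[s], 0.0, pattern)
    return SubjectCase(
        subject_id=base.subject_id + "_interv",
        nce=nce, cme=base.cme.copy(), nge=base.nge.copy(),
        roi_mask=base.roi_mask.copy(),
        true_uplift=dict(base.true_uplift),
    )


def save_cohort(cases: list[SubjectCase], out_dir: str | Path,
                voxel_spacing_mm: float = 3.0) -> list[Path]:
    """Write one NIfTI per volume plus a JSON sidecar of realised uplifts."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_spacing_mm] * 3 + [1.0])
    written = []
    for case in cases:
        for name, vol in (("nce", case.nce), ("cme", case.cme),
                          ("nge", case.nge)):
            p = out_dir / f"{case.subject_id}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), p)
            written.append(p)
        p = out_dir / f"{case.subject_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(case.roi_mask.astype(np.int16), affine), p)
        written.append(p)
        sidecar = out_dir / f"{case.subject_id}_uplift.json"
        payload = {f"{roi}_{PHASE_NAMES[ph]}": v
                   for (roi, ph), v in case.true_uplift.items()}
        sidecar.write_text(json.dumps(payload, indent=2))
        written.append(sidecar)
    return written
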