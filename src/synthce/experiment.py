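"""End-to-end experiment orchestration.

One YAML config drives the whole pipeline: phantom cohort generation with a
disjoint train/test split, training of one or more paradigms, stitched
full-volume inference on held-out subjects for both contrast phases,
image-quality evaluation (median [bootstrap 95% CI] of MSE / pSNR / SSIM per
model and phase) and the per-(model, ROI, phase) Bland-Altman bias table.
A manifest records the config snapshot, seed and artefact paths so a run can
be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biasstats import PairedMeans, BlandAltman, bootstrap_ci
from .ctdata import save_nifti
from .metrics import mse, psnr, sample_roi, ssim
from .nets import save_checkpoint
from .phantom import CME, NGE, PHASE_NAMES, PhantomSpec, ROI_LABELS, generate_cohort, save_cohort
from .stitch import StitchConfig, predict_hu
from .train import ExperimentConfig, TrainResult, train

__all__ = ["RunManifest", "load_config", "run_experiment",
           "evaluate_predictions", "bias_table", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "name": "experiment",
    "seed": 0,
    "phantom": {"grid_size": 64, "n_train": 10, "n_test": 4,
                "noise_sd_hu": 15.0, "voxel_spacing_mm": 3.0},
    "paradigms": ["supervised_baseline", "supervised_phase"],
    "train": {"steps": 300, "patch_size": 32, "gen_layers": 3,
              "gen_channels": 4, "disc_layers": 2, "disc_channels": 8},
    "stitch": {"stride": 16},
    "eval": {"n_boot": 500, "n_slices": 5},
    "out_dir": "runs/experiment",
    "save_volumes": False,
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    out_dir: str
    version: str = ""
    artefacts: dict = field(default_factory=dict)

    def save(self, path: str | Path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | dict | None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    if isinstance(path, dict):
        return _merge(DEFAULT_CONFIG, path)
    with open(path) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def _phase_generators(result: TrainResult):
    """Map phase -> (generator, conditioned_flag) for prediction."""
    out = {}
    for phase in (CME, NGE):
        gen = result.generator_for(phase)
        out[phase] = (gen, gen.spec.conditioned)
    return out


def predict_test_volumes(results: dict[str, TrainResult], test_cases,
                         stride: int, patch_size: int) -> pd.DataFrame:
    """Stitched HU predictions for every (model, test subject, phase)."""
    rows = []
    for model, result in results.items():
        for phase in (CME, NGE):
            gen, cond = _phase_generators(result)[phase]
            cfg = StitchConfig(patch_size=patch_size, stride=stride,
                               phase=phase if cond else None)
            for case in test_cases:
                pred = predict_hu(gen, case.nce, cfg)
                rows.append({"model": model, "phase": phase,
                             "subject_id": case.subject_id, "pred": pred})
    return pd.DataFrame(rows)


def evaluate_predictions(pred_rows: pd.DataFrame, test_cases,
                         n_boot: int = 500, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image-quality metrics per prediction plus the per-(model, phase)
    median [bootstrap 95% CI] summary table."""
    by_id = {c.subject_id: c for c in test_cases}
    per = []
    for _, row in pred_rows.iterrows():
        truth = by_id[row.subject_id].volume(row.phase)
        per.append({
            "model": row.model, "phase": row.phase,
            "subject_id": row.subject_id,
            "mse": mse(row.pred, truth),
            "psnr": psnr(row.pred, truth),
            "ssim": ssim(row.pred, truth),
        })
    per = pd.DataFrame(per)
    summary_rows = []
    for (model, phase), grp in per.groupby(["model", "phase"]):
        for metric in ("mse", "psnr", "ssim"):
            vals = grp[metric].to_numpy()
            lo, hi = bootstrap_ci(vals, np.median, n_boot=n_boot, seed=seed)
            summary_rows.append({
                "model": model, "phase": PHASE_NAMES[phase], "metric": metric,
                "median": float(np.median(vals)), "ci_low": lo, "ci_high": hi})
    return per, pd.DataFrame(summary_rows)


def roi_mean_table(pred_rows: pd.DataFrame, test_cases,
                   n_slices: int = 5) -> pd.DataFrame:
    """Per-(model, subject, roi, phase) mean HU of prediction and truth,
    sampled with the five-equally-spaced-slices protocol."""
    by_id = {c.subject_id: c for c in test_cases}
    rows = []
    for _, row in pred_rows.iterrows():
        case = by_id[row.subject_id]
        truth = case.volume(row.phase)
        for roi in ROI_LABELS:
            s_pred = sample_roi(case.roi_mask, row.pred, roi, n_slices,
                                case.subject_id, row.phase)
            s_true = sample_roi(case.roi_mask, truth, roi, n_slices,
                                case.subject_id, row.phase)
            if s_pred is None or s_true is None:
                continue
            rows.append({"model": row.model, "subject_id": case.subject_id,
                         "roi": roi, "phase": row.phase,
                         "pred_hu": s_pred.mean_hu, "true_hu": s_true.mean_hu})
    return pd.DataFrame(rows)


def bias_table(roi_means: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bland-Altman cell per (model, roi, phase): mean bias [+-LoA] (slope)."""
    rows = []
    for (model, roi, phase), grp in roi_means.groupby(["model", "roi", "phase"]):
        records = [PairedMeans.from_values(r.subject_id, r.pred_hu, r.true_hu,
                                           method=model, roi=roi, phase=phase)
                   for r in grp.itertuples()]
        res = BlandAltman(records).fit(alpha=alpha)
        rows.append({"model": model, "roi": roi, "phase": PHASE_NAMES[phase],
                     "mean_bias_hu": res.mean_bias,
                     "loa_half_width_hu": res.loa_half_width,
                     "slope": res.slope, "slope_p": res.slope_p,
                     "intercept_p": res.intercept_p,
                     "classification": res.classification,
                     "cell": res.cell()})
    return pd.DataFrame(rows)


def run_experiment(config: dict | str | Path | None = None,
                   seed: int | None = None,
                   out_dir: str | Path | None = None) -> RunManifest:
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    for p in cfg["paradigms"]:
        ExperimentConfig.for_paradigm(p)  # validate before any compute

    ss = np.random.SeedSequence(entropy=cfg["seed"])
    s_phantom, s_train, s_eval = ss.spawn(3)

    ph = cfg["phantom"]
    n_total = ph["n_train"] + ph["n_test"]
    spec = PhantomSpec(
        grid_size=ph["grid_size"], n_subjects=n_total,
        noise_sd_hu=ph["noise_sd_hu"],
        voxel_spacing_mm=ph.get("voxel_spacing_mm", 3.0),
        seed=int(s_phantom.generate_state(1)[0] % 2**31))
    cohort = generate_cohort(spec)
    train_cases = cohort[:ph["n_train"]]
    test_cases = cohort[ph["n_train"]:]

    tr = cfg["train"]
    results: dict[str, TrainResult] = {}
    artefacts: dict = {"checkpoints": {}, "logs": {}}
    for paradigm, s in zip(cfg["paradigms"], s_train.spawn(len(cfg["paradigms"]))):
        overrides = {k: tr[k] for k in
                     ("steps", "patch_size", "gen_layers", "gen_channels",
                      "disc_layers", "disc_channels", "lr_gen", "lr_disc",
                      "foreground_bias", "augment") if k in tr}
        tcfg = ExperimentConfig.for_paradigm(
            paradigm, seed=int(s.generate_state(1)[0] % 2**31), **overrides)
        result = train(tcfg, train_cases)
        results[paradigm] = result
        ckpt_dir = out / paradigm / "ckpt"
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        for key, gen in result.generators.items():
            save_checkpoint(gen, ckpt_dir / f"generator_{key}")
        log_path = out / paradigm / "log.csv"
        result.save_log(log_path)
        artefacts["checkpoints"][paradigm] = str(ckpt_dir)
        artefacts["logs"][paradigm] = str(log_path)

    pred_rows = predict_test_volumes(results, test_cases,
                                     stride=cfg["stitch"]["stride"],
                                     patch_size=tr["patch_size"])
    if cfg.get("save_volumes"):
        pred_dir = out / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for _, row in pred_rows.iterrows():
            save_nifti(row.pred, pred_dir / f"{row.subject_id}_{row.model}_"
                       f"{PHASE_NAMES[row.phase]}.nii.gz")
        artefacts["predictions"] = str(pred_dir)

    eval_seed = int(s_eval.generate_state(1)[0] % 2**31)
    per_image, quality = evaluate_predictions(
        pred_rows, test_cases, n_boot=cfg["eval"]["n_boot"], seed=eval_seed)
    roi_means = roi_mean_table(pred_rows, test_cases,
                               n_slices=cfg["eval"]["n_slices"])
    biases = bias_table(roi_means)

    paths = {
        "image_metrics": out / "image_metrics.csv",
        "image_quality_table": out / "image_quality_table.csv",
        "roi_means": out / "roi_means.csv",
        "bias_table": out / "bias_table.csv",
    }
    per_image.to_csv(paths["image_metrics"], index=False)
    quality.to_csv(paths["image_quality_table"], index=False)
    roi_means.to_csv(paths["roi_means"], index=False)
    biases.to_csv(paths["bias_table"], index=False)
    artefacts.update({k: str(v) for k, v in paths.items()})
    artefacts["train_subjects"] = [c.subject_id for c in train_cases]
    artefacts["test_subjects"] = [c.subject_id for c in test_cases]

    manifest = RunManifest(config=cfg, seed=cfg["seed"], out_dir=str(out),
                           version=__version__, artefacts=artefacts)
    manifest.save(out / "manifest.json")
    return manifest
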