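# synthce — multi-phase synthetic contrast enhancement for CT

Interventional CT guidance of renal cryoablation relies on iodinated
contrast agents to make the aorta, kidney and tumour visible, but contrast
washes out quickly, adds X-ray dose on re-administration, and can cause
allergic reactions and renal toxicity. `synthce` implements *synthetic*
contrast enhancement: a 3D convolutional generator maps a non-contrast CT
volume (NCE) to either the corticomedullary (CME, ~35 s post-injection) or
the nephrogenic (NGE, ~80 s) enhancement phase. A single network covers both
phases by **phase conditioning** — the scalar phase label t (1 = CME,
2 = NGE) is tiled as an extra constant channel onto each decoder layer's
input, so

    ŷ_t = f_θ(x, t)

replaces one trained network per phase. Three supervision regimes are
implemented around the same U-Net-style generator:

* **fully supervised** — ROI-weighted mean absolute error
  `L_ROI = μ·L_F + (1−μ)·L_B`, where `L_F`/`L_B` are the foreground
  (aorta + kidney + tumour) and background L1 terms and μ defaults to 0.2;
* **adversarial with supervision** (Pix2Pix-style) — a 3D PatchGAN
  discriminator with binary cross-entropy losses plus `λ·L_ROI` (λ = 720,
  μ = 0.1), dropout noise in the first three decoder layers at training
  *and* inference, and differentiable augmentation (shared translation,
  cut-out and intensity jitter) of every image the discriminator sees;
* **unpaired cycle-consistent** (CycleGAN-style) — forward/backward
  generator–discriminator pairs with least-squares adversarial terms, cycle
  consistency (weight λ = 10), identity loss (λ/2 = 5) and a 50-image replay
  buffer for discriminator updates.

Volumes are windowed to [−500, 2500] HU and normalised to [0, 1]; training
uses 64³ patches (32³ at demo scale) and whole volumes are predicted by
sliding-window inference with stride 16 and overlap averaging, then
converted back to Hounsfield units for evaluation.

Because clinical data cannot be shipped, the package includes a first-class
**phantom module**: synthetic abdominal cohorts (aorta tube, kidney
ellipsoids with a medullary core, a tumour sphere) with known per-subject
enhancement drawn from truncated normal distributions, so every downstream
claim is testable against ground truth. The evaluation stack mirrors the
clinical protocol: MSE / pSNR / SSIM in HU (peak 65535), ROI intensity
sampling on five equally spaced slices, Bland–Altman bias analysis with 95%
limits of agreement and constant-vs-proportional classification, ANCOVA
method comparison with Bonferroni-corrected pairwise contrasts, bootstrap
confidence intervals, rank tests, and a downstream 2D tumour-segmentation
task scored by Dice.

The neural-network core (N-d convolution/transpose convolution, instance
normalisation, dropout, reverse-mode autodiff, Adam, He initialisation) is a
compact numpy implementation in `synthce.nn`, verified against numerical
gradients in the test suite.

## Worked example

```python
from synthce.phantom import PhantomSpec, generate_cohort, CME, NGE
from synthce.train import ExperimentConfig, train
from synthce.stitch import StitchConfig, predict_hu

cohort = generate_cohort(PhantomSpec(grid_size=64, n_subjects=11, seed=101))
cfg = ExperimentConfig.for_paradigm(
    "supervised_phase", steps=3000, patch_size=32,
    gen_layers=3, gen_channels=4, lr_gen=1e-3, seed=5)
result = train(cfg, cohort[:10])

case = cohort[10]                       # held-out subject
gen = result.generators["conditioned"]
for phase, name in [(CME, "CME"), (NGE, "NGE")]:
    pred = predict_hu(gen, case.nce, StitchConfig(32, 16, phase=phase))
    up = (pred - case.nce)[case.roi_mask == 1].mean()
    print(f"{name}: predicted aorta uplift {up:.0f} HU "
          f"(truth {case.true_uplift[('aorta', phase)]:.0f} HU)")
```

Output from this exact script:

```
CME: predicted aorta uplift 168 HU (truth 198 HU)
NGE: predicted aorta uplift 88 HU (truth 73 HU)
```

The same conditioned network, switched only by the tiled phase label,
produces the strong corticomedullary aortic enhancement and the weaker
nephrogenic one in the physiologically correct order.

The full pipeline — simulate, train, stitched prediction on held-out
subjects, image-quality table (median [bootstrap 95% CI] of MSE/pSNR/SSIM)
and per-(model, ROI, phase) Bland–Altman bias table — runs from one config:

```bash
synthce run-all --config configs/demo.yaml --seed 0 --out runs/demo
```

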