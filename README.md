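# tomodensity

Automated percent breast density (PD) measurement for digital breast
tomosynthesis (DBT), for imaging scientists and breast-cancer epidemiologists
who need density-based risk measures from reconstructed slice stacks and
synthetic 2D views.

## What it computes

**Detection.** Dense fibroglandular tissue carries elevated high-frequency
variance relative to adipose tissue (signal-dependent noise). The detector
labels an image in two stages: a high-pass wavelet residual is tiled into
non-overlapping n×n boxes (n = 4); the unbiased box variance s² is tested
against a global adipose reference σ²_ref with the statistic
(n²−1)·s²/σ²_ref, labeled dense when it exceeds the upper-tail χ² quantile
at significance 0.1 with n²−1 = 15 degrees of freedom. Stage 1 estimates
σ²_ref over the whole breast area (bias-corrected median of box variances);
stage 2 re-estimates it from the stage-1 non-dense boxes and relabels every
box. Optionally — and by default, since it improves behaviour on heavily
processed images — the image is first multiplied elementwise by a
zero-mean, unit-variance Gaussian field.

**Volumetrics.** For N slices of thickness t (mm) and pixel area A (mm²),
with n_i breast pixels and d_i dense pixels in slice i:

    BV     = t·A·Σ n_i                breast volume
    D_v    = t·A·Σ d_i                dense tissue volume
    PD_vol = 100·Σd_i / Σn_i          volumetric percent density
    PD_m   = (100/N)·Σ(d_i/n_i)       slice-mean percent density
    PT     = N·⟨d_i⟩                  projected total of the summed labels

PD_vol ≡ PD_m when the breast area is constant across slices. Dividing the
summed label image by N and scaling to percent gives the standardized
synthetic image s(x,y): each pixel is the percentage of slices labeled dense
above that location (parallel-beam approximation).

**Depth profiling.** Per-slice PD is modeled as PD = a + b·P + c·P²
over normalized depth P ∈ [1, 100] (support surface → compression paddle);
concave-down fits peak at P = −b/(2c). Coefficients can be compared across
groups with Welch t-tests.

**Cohort statistics.** Association with case status in 1:1 matched pairs is
estimated by conditional logistic regression — equivalently a no-intercept
logistic fit on within-pair (case − control) covariate differences — with
the measure log-transformed and scaled to SD units, giving an odds ratio per
SD with a Wald 95% CI, plus rank-based AUC (Az) with a DeLong CI and Pearson
correlations with BMI.

A seeded phantom module generates two-texture slices, volumes with a
quadratic ground-truth density profile, max-projection 2D views, and matched
cohorts drawn from the conditional logistic model, so every layer can be
validated against known truth.

## Worked example

```python
from tomodensity import (PhantomSpec, DetectionParams, make_volume, make_cview,
                         density_panel, label_volume, DepthProfile, fit_quadratic)

spec = PhantomSpec(image_shape=(256, 200), n_slices=30, cbt_mm=30.0, seed=7)
volume, truth = make_volume(spec)
panel = density_panel(volume, make_cview(volume), DetectionParams(seed=7))
print(panel.to_frame().round(3).to_string(index=False))

labeled = label_volume(volume, DetectionParams(seed=7))
fit = fit_quadratic(DepthProfile.from_slice_pd(labeled.pd_i))
print(round(fit.p_peak, 2))
```

prints

```
 BV_mm3  Dv_mm3  PD_vol   PD_m   m_vol  v_vol   m_syn  PD_syn  PD_central  PD_max  P_at_max
 8177.7 2667.84  32.623 32.623 242.761 85.942 805.278  19.076      34.337  35.863    48.793
41.81
```

BV and D_v are the breast and dense volumes in mm³; PD_vol and PD_m agree
exactly because the phantom uses one breast mask for all slices. The
phantom's true volumetric dense fraction is 21.4%; the detected 32.6%
includes the detector's null rate (at significance 0.1 roughly 10–15% of
adipose boxes exceed the χ² cutoff by construction), so detected PD is a
relative measure sitting above truth by a predictable offset. The fitted
depth profile peaks at P ≈ 41.8, close to the generator's concave-down
profile maximum at 43.75.

The same workflow is available from the shell:

```sh
tomodensity simulate-cohort --pairs 426 --log-or 0.37 --seed 7 --out cohort.csv
tomodensity cohort --in cohort.csv --out or.json
# OR per SD = 1.60 (1.35, 1.90), Az = 0.62
```

Other commands: `simulate-volume`, `detect`, `measure`, `profile`,
`profile-compare`, `cohort-summary`, and `run` (full pipeline with a
manifest). See `tomodensity --help`.

## Layout

- `tomodensity.phantom` — seeded generators (slices, volumes, 2D views, cohorts)
- `tomodensity.detection` — the two-stage density detector
- `tomodensity.volumetrics` — BV, D_v, PD_vol, PD_m, projections, panels
- `tomodensity.slice_profile` — quadratic depth model and group comparison
- `tomodensity.cohort_stats` — conditional logistic regression, Az, summaries
- `tomodensity.io`, `tomodensity.cli`, `tomodensity.pipeline` — formats, CLI, end-to-end runs

See `docs/methods.md` for modeling assumptions, parameter choices, and known
limitations.
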