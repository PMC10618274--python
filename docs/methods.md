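# Methods

## The detection model

The detector treats density labeling as repeated local hypothesis testing.
Let the high-pass wavelet residual of an image have adipose band variance
σ². For a 4×4 box of residual pixels with unbiased sample variance s², the
statistic 15·s²/σ² is approximately χ²₁₅ under the adipose null (exactly so
for iid Gaussian residuals), and a box is labeled dense when the statistic
exceeds the upper-tail quantile at significance α = 0.1. Two stages refine
the reference: stage 1 estimates σ² from all breast boxes; stage 2 from the
boxes stage 1 left non-dense, then relabels everything.

Assumptions worth stating plainly:

- **The χ² null is approximate, not exact.** High-pass filtering correlates
  neighbouring residual pixels, and the optional noise multiplication makes
  the residual distribution heavier-tailed than Gaussian. Both effects
  disperse the box-variance distribution, so the realized null rate at
  α = 0.1 is ~0.12–0.13 rather than 0.10. The test suite asserts the
  empirical band and strict monotonicity in α rather than exact calibration.
- **Detected PD is a relative measure.** By construction the detector labels
  ≈ α (or slightly more, see above) of truly adipose boxes dense. On an
  image with true dense fraction f this inflates measured PD by roughly
  (1 − f/100)·α·100 percentage points (≈ +12 pp at f = 20, α = 0.1). The
  measure orders subjects by density — which is what association analyses
  need — but is not an unbiased estimate of the anatomical dense fraction.
  Sub-percent absolute accuracy at α = 0.1 is arithmetically impossible, and
  the suite documents this as expected behaviour rather than hiding it.
- **Noise multiplication** (image × N(0,1) field) converts local mean into
  local variance: var(v·Z) = v² for a constant v. Dense tissue is brighter
  as well as more textured, so the step adds the mean contrast to the
  variance contrast. Why it helps empirically on heavily processed clinical
  images is an open question; here it is implemented as a seeded,
  reproducible preprocessing step and its calibration consequences are
  measured, not assumed.

### Numerical choices

- Wavelet: single-level `db2`, high-pass = image − reconstructed
  approximation (zero DC response; shape preserved; odd dimensions cropped
  after reconstruction). Wavelet name and level are configurable; the method
  is wavelet-generic.
- Box tiling: non-overlapping boxes on a fixed grid anchored at the image
  origin. Boxes containing any out-of-mask pixel are excluded from
  reference estimation and are never labeled dense; their pixels still count
  in the breast area n_i. This makes box counts well-defined and lets a
  naive-loop oracle reproduce the labeling exactly.
- Reference variance: median of eligible box variances divided by
  q₀.₅(χ²₁₅)/15 ≈ 0.956. The median resists dense-tissue contamination in
  stage 1; the correction removes the χ² median bias under the null.
- Fewer than 10 eligible boxes is an error ("insufficient adipose
  reference"); fewer than 100 raises a warning and sets a `degenerate` flag
  in the result metadata.
- Pixel spacing (85–106 μm across acquisitions) does not rescale the
  algorithm: the box is fixed in pixels. Spacing enters only through the
  pixel area A in the volumetric measures.

## Volumetric measures

BV, D_v, PD_vol, PD_m, PT/NPT and s(x,y) are pure arithmetic on the
per-slice label counts; the only modeling content is bookkeeping:

- PD_vol ≡ PD_m exactly when n_i is constant; the test suite checks the
  identity to 1e-9 on constant-mask phantoms, and the phantom's optional
  per-slice mask erosion breaks it deliberately.
- The projection domain is the union of slice masks; pixels outside a
  slice's mask count as non-dense in that slice. Σproj = Σd_i is an integer
  identity.
- Central slice for even N: index round((N+1)/2).
- m_vol/v_vol/m_syn are computed within breast masks only. Including
  background would shift absolute values; in-mask is the defensible
  convention and is applied uniformly.
- s(x,y) exports rescale 0–100 → 0–255 into 8-bit PNG.

## Depth profile model

P = 1 + 99·(i−1)/(N−1) maps slice i ∈ [1, N] onto [1, 100]; physical depth
is recovered approximately by (P/100)·CBT. A single-slice volume has no
depth axis (P = 50 by convention, warned). The quadratic is fit by OLS on
the design (1, P, P²); any 3 points with distinct P are interpolated with
zero residual; the peak is −b/(2c) with flags for c ≥ 0 and out-of-range
peaks.

**Peak identifiability.** The peak of a nearly flat quadratic is a ratio of
two small, noisy coefficients and is not statistically identifiable: with
2-pp per-slice noise, N = 50, the coefficient SE is ≈ 3.9e-4, so a
curvature of c = −0.0008 (|c|/SE ≈ 2) yields mean peak errors near 10 depth
units, while c = −0.0016 (|c|/SE ≈ 4) yields ≈ 3. The Monte Carlo recovery
test therefore uses (a, b, c) = (20, 0.14, −0.0016) — same peak location,
43.75 — while the phantom's default profile stays the shallower
(20, 0.07, −0.0008). Group comparison uses Welch (unequal-variance) t-tests;
histogram exports use Freedman–Diaconis binning.

## Matched-pair statistics

For 1:1 matching the conditional likelihood is exactly a no-intercept
logistic regression on within-pair (case − control) differences with all
outcomes 1; the fit uses Newton iterations (statsmodels) to tight tolerance,
so a binary exposure reproduces log(n₁₀/n₀₁) to machine precision. Choices:

- SD for per-SD scaling: computed on log-transformed values over the pooled
  sample (cases + controls). Centering is omitted — the conditional
  likelihood is location-invariant.
- Ethnicity: binary indicator from the two informative levels;
  "unknown" values drop the whole pair (the conditional likelihood needs
  both members).
- CIs: Wald, exp(β ± 1.96·SE).
- Az: midrank AUC of the fitted linear predictor; variance by the DeLong
  structural-component estimator; a constant predictor returns 0.5 flagged
  degenerate.
- BMI outlier rule for correlations: exclude |z| > 3 on the x variable,
  configurable. Other criteria would shift correlations slightly.

## The phantom: what it emulates and what it does not

The generator reproduces the *statistical premises* of the method, not
breast anatomy:

- Two Gaussian textures, independent per pixel: adipose (mean 200, SD 20)
  and dense (mean 400, SD 40) on the 10-bit scale, quantized to integers.
  These values put the dense/adipose detail-band variance ratio at exactly
  4 both with noise multiplication (mean²+SD² ratio) and without (SD²
  ratio). Real tissue has spatially correlated texture; the phantom's white
  texture is the simplest model under which local variance discriminates
  classes, so passing tests validate the estimator logic, not clinical
  performance.
- Dense geometry: random ellipses (axes 5–25 px) accumulated until the
  slice's target PD is met within ±1 pp, the final ellipse shrunk to fit
  the budget. Contiguous blobs mimic fibroglandular clustering; real
  parenchyma is far more structured.
- Per-slice target PD follows a concave-down quadratic in P (default
  (20, 0.07, −0.0008), peak 43.75); the breast mask (half-ellipse, ~53% of
  the frame) is constant across slices unless erosion is requested.
- The 2D synthetic view is a max-intensity projection with a monotone
  contrast rescale — a stand-in for the manufacturer's proprietary
  processed projection, with no claim of equivalence.
- Cohorts: log-density ~ N(log 21.6, 0.09) (measure scale and spread chosen
  to match a screening population's PD distribution), BMI ~ N(28.7, 6.7)
  with correlation −0.4 to log density, ethnicity Bernoulli(0.18). Case
  assignment within a pair follows the exact 1:1 conditional logistic model,
  so the fitter is evaluated against a correctly specified truth; model
  misspecification robustness is out of scope.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to keep the full suite
fast while leaving every estimator in its operating regime: 512×400 single
slices (≈ 6,000 complete boxes) for detector calibration and recall,
128×100 × 8–10-slice volumes for the volumetric identities, 200 replicates
for profile recovery, and 500 replicate cohorts of 426 pairs for OR
recovery, coverage, and type-I error.

## Known limitations

- Absolute PD is inflated by the null rate (see above); comparisons across
  detectors or with anatomical ground truth should treat it as a monotone
  score.
- The χ² calibration degrades for very small breast areas (flagged) and for
  wavelets/levels that strongly correlate residuals within a box.
- No scanner physics, reconstruction artifacts, or anthropomorphic anatomy
  in the phantom; pectoral muscle and non-cranio-caudal views are out of
  scope.
- Risk-prediction model building is out of scope: the matched design
  identifies associations (ORs), not absolute risk.
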