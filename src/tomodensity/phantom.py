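"""Seeded synthetic phantoms and cohorts for desk-scale experiments.

The phantom emulates the statistical structure the detector and the
association statistics assume, not breast anatomy: adipose background and
dense inclusions are two Gaussian textures that differ in mean and variance
(so dense regions carry elevated high-frequency variance), per-slice dense
fraction follows a concave-down quadratic in normalized depth, and matched
case-control pairs are drawn from a conditional logistic model with a
specified per-SD log odds ratio and a negative BMI-density correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort_stats import MatchedCohort
from .slice_profile import normalize_depth
from .types import GrayImage2D, TomoVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "make_breast_mask",
    "make_slice",
    "make_volume",
    "make_cview",
    "make_cohort",
]

TEN_BIT_MAX = 1023


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of a synthetic DBT acquisition.

    Texture defaults put the dense detail-band variance at 4x the adipose
    one both with and without the noise-multiplication preprocessing
    (multiplying by N(0,1) turns a (mu, sigma) texture into white noise of
    variance mu^2 + sigma^2, and (400^2+40^2)/(200^2+20^2) = 4 exactly).
    ``dense_fraction_profile`` gives the per-slice target PD (percent) as a
    quadratic a + b*P + c*P^2 in normalized depth P in [1, 100].
    """

    image_shape: tuple[int, int] = (512, 400)
    pixel_spacing_mm: float = 0.1
    slice_thickness_mm: float = 1.0
    n_slices: int = 50
    cbt_mm: Optional[float] = None
    adipose_mean: float = 200.0
    adipose_sigma: float = 20.0
    dense_mean: float = 400.0
    dense_sigma: float = 40.0
    dense_fraction_profile: tuple[float, float, float] = (20.0, 0.07, -0.0008)
    n_dense_blobs_per_slice: int = 12
    side: str = "left"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cbt_mm is None:
            self.cbt_mm = self.n_slices * self.slice_thickness_mm
        if self.dense_sigma <= self.adipose_sigma:
            raise ValueError("dense_sigma must exceed adipose_sigma (detectability premise)")
        if abs(self.n_slices - self.cbt_mm / self.slice_thickness_mm) > 1.5:
            raise ValueError("n_slices must be approximately cbt_mm / slice_thickness_mm")
        for v in (self.adipose_mean, self.dense_mean):
            if not (0 <= v <= TEN_BIT_MAX):
                raise ValueError("tissue means must lie in the 10-bit range [0, 1023]")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")

    def target_pd(self, slice_index: int) -> float:
        """Target percent density of slice ``slice_index`` (1-based)."""
        a, b, c = self.dense_fraction_profile
        p = normalize_depth(slice_index, self.n_slices)
        return a + b * p + c * p * p


@dataclass
class GroundTruth:
    """Pixel-exact dense masks the generator actually realized."""

    dense_masks: list[np.ndarray]
    d_i_true: np.ndarray = field(init=False)
    n_i_true: np.ndarray = field(init=False)
    breast_masks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.breast_masks:
            raise ValueError("breast_masks required")
        self.d_i_true = np.array([m.sum() for m in self.dense_masks], dtype=int)
        self.n_i_true = np.array([m.sum() for m in self.breast_masks], dtype=int)
        if np.any(self.d_i_true > self.n_i_true):
            raise ValueError("dense count cannot exceed breast count")


@dataclass
class CohortSpec:
    """Parameters of the simulated 1:1 matched case-control cohort.

    ``true_log_or_per_sd`` is the log odds ratio per one SD of the
    log-transformed density measure; ``bmi_density_corr`` the (negative)
    correlation between BMI and log density; ``bmi_log_or`` the per-unit
    (kg/m^2) log odds ratio of BMI.  Marginal scales mirror a screening
    population: log-density ~ N(log 21.6, 0.09), BMI ~ N(28.7, 6.7),
    ethnicity a binary indicator with 18% prevalence.
    """

    n_pairs: int = 426
    true_log_or_per_sd: float = 0.37
    bmi_density_corr: float = -0.4
    bmi_log_or: float = 0.05
    ethnicity_log_or: float = -0.5
    seed: int = 0

    # marginal scales of the latent measures
    log_measure_mean: float = math.log(21.6)
    log_measure_sd: float = 0.09
    bmi_mean: float = 28.7
    bmi_sd: float = 6.7
    ethnicity_prevalence: float = 0.18

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (abs(self.bmi_density_corr) < 1):
            raise ValueError("|bmi_density_corr| must be < 1")
        if abs(self.true_log_or_per_sd) > 5:
            raise ValueError("|true_log_or_per_sd| > 5 gives degenerate separation")


def make_breast_mask(
    image_shape: tuple[int, int], side: str = "left"
) -> np.ndarray:
    """Half-ellipse breast-area mask flush with one lateral image edge."""
    rows, cols = image_shape
    if rows < 16 or cols < 16:
        raise ValueError(f"degenerate image shape {image_shape}")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    rr, cc = np.mgrid[:rows, :cols]
    semi_r = 0.45 * rows
    semi_c = 0.75 * cols
    mask = ((rr - rows / 2.0) / semi_r) ** 2 + (cc / semi_c) ** 2 <= 1.0
    if side == "right":
        mask = mask[:, ::-1]
    return mask


def _add_ellipse(
    dense: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    max_new_px: int,
) -> None:
    """Place one random ellipse inside the mask, in place.

    Axes are drawn from 5-25 px and shrunk if the full ellipse would exceed
    ``max_new_px``, so the realized dense fraction can always land within
    the +-1 pp tolerance of its target.
    """
    rows, cols = mask.shape
    in_mask = np.flatnonzero(mask)
    center = in_mask[rng.integers(in_mask.size)]
    r0, c0 = divmod(center, cols)
    ar, ac = rng.uniform(5, 25, size=2)
    if math.pi * ar * ac > max_new_px:
        scale = math.sqrt(max_new_px / (math.pi * ar * ac))
        ar, ac = max(2.0, ar * scale), max(2.0, ac * scale)
    theta = rng.uniform(0, math.pi)
    half = int(math.ceil(max(ar, ac))) + 1
    rlo, rhi = max(0, r0 - half), min(rows, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(cols, c0 + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    x = (rr - r0) * math.cos(theta) + (cc - c0) * math.sin(theta)
    y = -(rr - r0) * math.sin(theta) + (cc - c0) * math.cos(theta)
    ell = (x / ar) ** 2 + (y / ac) ** 2 <= 1.0
    dense[rlo:rhi, clo:chi] |= ell & mask[rlo:rhi, clo:chi]


def _dense_mask_for_target(
    mask: np.ndarray, target_percent: float, rng: np.random.Generator
) -> np.ndarray:
    """Union of random ellipses with dense fraction within +-1 pp of target."""
    dense = np.zeros_like(mask)
    if target_percent <= 0:
        return dense
    area = int(mask.sum())
    target_px = target_percent / 100.0 * area
    budget_px = (target_percent + 1.0) / 100.0 * area
    for _ in range(100_000):
        current = int(dense.sum())
        if current >= target_px:
            break
        _add_ellipse(dense, mask, rng, max_new_px=int(budget_px - current))
    return dense


def make_slice(
    spec: PhantomSpec,
    slice_index: int,
    seed: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
) -> tuple[GrayImage2D, np.ndarray]:
    """Generate one slice and its realized dense mask.

    Adipose background is Gaussian texture (adipose_mean, adipose_sigma);
    dense ellipses use (dense_mean, dense_sigma) and are added until the
    slice's target PD (the quadratic profile at this slice's depth) is met
    within one percentage point.  Pixels outside the breast mask are zero;
    intensities are quantized to integers in [0, 1023] to mimic the 10-bit
    stored scale.
    """
    if not (1 <= slice_index <= spec.n_slices):
        raise ValueError(f"slice_index {slice_index} outside [1, {spec.n_slices}]")
    target = spec.target_pd(slice_index)
    if target < 0 or target > 95:
        raise ValueError(f"target PD {target:.1f}% outside [0, 95]")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if mask is None:
        mask = make_breast_mask(spec.image_shape, spec.side)
    dense = _dense_mask_for_target(mask, target, rng)

    pixels = np.zeros(spec.image_shape, dtype=float)
    pixels[mask] = rng.normal(spec.adipose_mean, spec.adipose_sigma, int(mask.sum()))
    if dense.any():
        pixels[dense] = rng.normal(spec.dense_mean, spec.dense_sigma, int(dense.sum()))
    pixels = np.clip(np.rint(pixels), 0, TEN_BIT_MAX)
    image = GrayImage2D(pixels=pixels, mask=mask, pixel_spacing_mm=spec.pixel_spacing_mm)
    return image, dense


def make_volume(
    spec: PhantomSpec, erosion_per_slice: int = 0
) -> tuple[TomoVolume, GroundTruth]:
    """Generate a full volume whose per-slice PD follows the quadratic profile.

    The breast mask is constant across slices by default (so the volumetric
    and slice-mean PD measures coincide exactly); ``erosion_per_slice`` > 0
    erodes the mask progressively with depth to create unequal per-slice
    breast areas on purpose.
    """
    a, b, c = spec.dense_fraction_profile
    grid = np.linspace(1, 100, 397)
    profile = a + b * grid + c * grid * grid
    if profile.min() < 0:
        raise ValueError("dense fraction profile goes negative on [1, 100]")

    base_mask = make_breast_mask(spec.image_shape, spec.side)
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_slices)
    slices: list[GrayImage2D] = []
    dense_masks: list[np.ndarray] = []
    breast_masks: list[np.ndarray] = []
    for i in range(1, spec.n_slices + 1):
        mask = base_mask
        if erosion_per_slice > 0 and i > 1:
            mask = ndimage.binary_erosion(
                base_mask, iterations=erosion_per_slice * (i - 1)
            )
        img, dense = make_slice(spec, i, seed=int(child_seeds[i - 1]), mask=mask)
        slices.append(img)
        dense_masks.append(dense)
        breast_masks.append(mask)
    volume = TomoVolume(
        slices=slices, slice_thickness_mm=spec.slice_thickness_mm, cbt_mm=spec.cbt_mm
    )
    truth = GroundTruth(dense_masks=dense_masks, breast_masks=breast_masks)
    return volume, truth


def make_cview(volume: TomoVolume) -> GrayImage2D:
    """Synthetic 2D view: per-pixel max projection, rescaled to 10 bits.

    A deliberately simple stand-in for the manufacturer's processed 2D
    synthetic mammogram; it preserves the location of dense structure (a
    bright blob in any slice stays bright in the projection) under a
    monotone contrast rescale.
    """
    if volume.n_slices < 1:
        raise ValueError("empty volume")
    stack = volume.pixel_stack()
    proj = stack.max(axis=0)
    lo, hi = proj.min(), proj.max()
    if hi > lo:
        proj = (proj - lo) / (hi - lo) * TEN_BIT_MAX
    pixels = np.clip(np.rint(proj), 0, TEN_BIT_MAX)
    union = np.logical_or.reduce(volume.mask_stack(), axis=0)
    return GrayImage2D(
        pixels=pixels, mask=union, pixel_spacing_mm=volume.pixel_spacing_mm
    )


def make_cohort(spec: CohortSpec) -> MatchedCohort:
    """Simulate a 1:1 matched case-control cohort.

    Each subject gets a latent log-normal density measure, a BMI negatively
    correlated with log density, and a binary ethnicity indicator.  Within
    each pair, which member is the case follows the 1:1 conditional logistic
    model: P(subject 1 is the case) = sigmoid(eta_1 - eta_2) with linear
    predictor eta = beta_sd * z_density + beta_bmi * BMI + beta_eth * eth,
    where z_density standardizes log density by its generating SD.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    rho = spec.bmi_density_corr

    z_d = rng.standard_normal((n, 2))
    z_b = rho * z_d + math.sqrt(1 - rho * rho) * rng.standard_normal((n, 2))
    log_measure = spec.log_measure_mean + spec.log_measure_sd * z_d
    measure = np.exp(log_measure)
    bmi = np.clip(spec.bmi_mean + spec.bmi_sd * z_b, 15.0, None)
    eth = (rng.random((n, 2)) < spec.ethnicity_prevalence).astype(int)

    eta = (
        spec.true_log_or_per_sd * z_d
        + spec.bmi_log_or * bmi
        + spec.ethnicity_log_or * eth
    )
    p_first_is_case = 1.0 / (1.0 + np.exp(eta[:, 1] - eta[:, 0]))
    first_case = rng.random(n) < p_first_is_case

    rows = []
    for i in range(n):
        case_j = 0 if first_case[i] else 1
        for j in (case_j, 1 - case_j):
            rows.append(
                {
                    "pair_id": i + 1,
                    "status": "case" if j == case_j else "control",
                    "bmi": bmi[i, j],
                    "ethnicity": "hispanic" if eth[i, j] else "non-hispanic",
                    "measure": measure[i, j],
                }
            )
    return MatchedCohort(pd.DataFrame(rows))
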