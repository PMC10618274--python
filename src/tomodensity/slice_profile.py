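"""Percent density as a function of depth through the compressed breast.

Per-slice PD is modeled as a second-degree polynomial in the normalized
depth P in [1, 100] (P = 1 at the breast support surface, P = 100 at the
compression paddle):

    PD(P) = a + b*P + c*P^2

Concave-down fits (c < 0) place the PD maximum at P = -b/(2c); across a
cohort the distribution of that peak and of the coefficients can be compared
between case and control groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthProfile",
    "QuadFit",
    "normalize_depth",
    "fit_quadratic",
    "peak_location",
    "compare_groups",
]


def normalize_depth(slice_index: int, n_slices: int) -> float:
    """Map 1-based slice index to normalized depth P in [1, 100].

    P = 1 + 99*(i-1)/(N-1), so i=1 -> 1 (support surface) and i=N -> 100
    (paddle); physical distance is recovered approximately by
    (P/100) * compressed breast thickness.  A single-slice volume has no
    depth axis; P = 50 by convention, with a warning.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not (1 <= slice_index <= n_slices):
        raise ValueError(f"slice_index {slice_index} outside [1, {n_slices}]")
    if n_slices == 1:
        warnings.warn("single-slice volume: normalized depth set to 50", stacklevel=2)
        return 50.0
    return 1.0 + 99.0 * (slice_index - 1) / (n_slices - 1)


@dataclass
class DepthProfile:
    """Per-slice PD values with their normalized depths."""

    P: np.ndarray
    pd: np.ndarray
    cbt_mm: float | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.pd = np.asarray(self.pd, dtype=float)
        if self.P.shape != self.pd.shape or self.P.ndim != 1:
            raise ValueError("P and pd must be 1D arrays of equal length")
        if np.any(np.diff(self.P) <= 0):
            raise ValueError("P must be strictly increasing")

    @classmethod
    def from_slice_pd(cls, pd_values: Sequence[float], cbt_mm: float | None = None) -> "DepthProfile":
        n = len(pd_values)
        P = np.array([normalize_depth(i, n) for i in range(1, n + 1)])
        return cls(P=P, pd=np.asarray(pd_values, dtype=float), cbt_mm=cbt_mm)


@dataclass
class QuadFit:
    """OLS fit PD = a + b*P + c*P^2 for one volume."""

    a: float
    b: float
    c: float
    rss: float
    n_points: int

    @property
    def p_peak(self) -> float:
        """Stationary point -b/(2c); NaN for a linear profile (c = 0)."""
        if self.c == 0:
            return float("nan")
        return -self.b / (2.0 * self.c)

    def predict(self, P: np.ndarray) -> np.ndarray:
        P = np.asarray(P, dtype=float)
        return self.a + self.b * P + self.c * P * P


def fit_quadratic(profile: DepthProfile) -> QuadFit:
    """Ordinary least squares on the design (1, P, P^2)."""
    P, y = profile.P, profile.pd
    if np.unique(P).size < 3:
        raise ValueError("need at least 3 distinct depths to fit a quadratic")
    X = np.column_stack([np.ones_like(P), P, P * P])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design")
    resid = y - X @ coef
    return QuadFit(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        rss=float(resid @ resid),
        n_points=len(y),
    )


def peak_location(fit: QuadFit) -> dict:
    """Locate the profile's stationary point and classify it.

    Returns the depth P = -b/(2c), whether it falls inside [1, 100], and
    whether the profile is concave-down (c < 0, interior maximum).  A linear
    profile (c = 0) has no stationary point and is flagged undefined.
    """
    if fit.c == 0:
        return {
            "p_peak": float("nan"),
            "in_range": False,
            "concave_down": False,
            "defined": False,
        }
    p = fit.p_peak
    return {
        "p_peak": p,
        "in_range": bool(1.0 <= p <= 100.0),
        "concave_down": fit.c < 0,
        "defined": True,
    }


def _group_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    return mean, se


def compare_groups(
    fits_a: Sequence[QuadFit], fits_b: Sequence[QuadFit]
) -> pd.DataFrame:
    """Welch t-tests per coefficient between two groups of fitted volumes.

    One row per coefficient (a, b, c) plus a row for the per-volume peak
    location: group means, standard errors, Welch t statistic, and p-value.
    Peaks enter as the empirical stationary point of each volume's fit,
    restricted to volumes with a defined, in-range, concave-down peak.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need at least 2 fits per group")

    rows = []
    for name in ("a", "b", "c"):
        va = np.array([getattr(f, name) for f in fits_a], dtype=float)
        vb = np.array([getattr(f, name) for f in fits_b], dtype=float)
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        (ma, sa), (mb, sb) = _group_stats(va), _group_stats(vb)
        rows.append(
            {
                "quantity": name,
                "mean_a": ma,
                "se_a": sa,
                "mean_b": mb,
                "se_b": sb,
                "t": float(t),
                "p_value": float(p),
            }
        )

    def _peaks(fits: Sequence[QuadFit]) -> np.ndarray:
        out = []
        for f in fits:
            loc = peak_location(f)
            if loc["defined"] and loc["in_range"] and loc["concave_down"]:
                out.append(loc["p_peak"])
        return np.array(out, dtype=float)

    pa, pb = _peaks(fits_a), _peaks(fits_b)
    if pa.size >= 2 and pb.size >= 2:
        t, p = stats.ttest_ind(pa, pb, equal_var=False)
        (ma, sa), (mb, sb) = _group_stats(pa), _group_stats(pb)
        rows.append(
            {
                "quantity": "p_peak",
                "mean_a": ma,
                "se_a": sa,
                "mean_b": mb,
                "se_b": sb,
                "t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def coefficient_histograms(
    fits: Sequence[QuadFit], coefficient: str
) -> pd.DataFrame:
    """Normalized histogram of one coefficient, Freedman-Diaconis binning."""
    vals = np.array([getattr(f, coefficient) for f in fits], dtype=float)
    edges = np.histogram_bin_edges(vals, bins="fd")
    counts, edges = np.histogram(vals, bins=edges, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": counts}
    )
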