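"""Matched case-control association statistics.

Association of an image measure with case status is estimated by 1:1
conditional logistic regression: with exactly one case and one control per
matched pair, the conditional likelihood reduces to a logistic model with no
intercept on the within-pair (case - control) covariate differences, all
outcomes equal to one.  Measures are log-transformed and scaled by the SD of
the log values over the pooled sample, so the reported odds ratio is per one
SD increment.  Discrimination is summarized by the rank-based AUC (Az) with
a DeLong-type confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MatchedCohort",
    "ORResult",
    "standardize_per_sd",
    "clogit_pairs",
    "az_discrimination",
    "pearson_r",
    "cohort_summary",
    "pooled_mean",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MatchedCohort:
    """A 1:1 matched case-control table.

    ``data`` must contain ``pair_id``, ``status`` ('case'/'control'),
    ``bmi``, ``ethnicity`` and one or more measure columns; every pair_id
    must appear exactly once as a case and once as a control.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"pair_id", "status"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        counts = self.data.groupby("pair_id")["status"].value_counts().unstack(fill_value=0)
        if not (
            set(counts.columns) == {"case", "control"}
            and (counts == 1).all().all()
        ):
            raise ValueError("every pair must have exactly one case and one control")

    @property
    def n_pairs(self) -> int:
        return self.data["pair_id"].nunique()

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(cases, controls), each sorted by pair_id."""
        cases = self.data[self.data["status"] == "case"].sort_values("pair_id")
        controls = self.data[self.data["status"] == "control"].sort_values("pair_id")
        return cases.reset_index(drop=True), controls.reset_index(drop=True)


@dataclass
class ORResult:
    """Per-SD odds ratio for one measure, with Wald CI and discrimination."""

    measure_name: str
    sd_used: float
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    az: float
    az_ci_low: float
    az_ci_high: float
    adjusted: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_value <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if not (0.0 <= self.az <= 1.0):
            raise ValueError("Az must lie in [0, 1]")


def standardize_per_sd(
    values: np.ndarray, log_transform: bool = True
) -> tuple[np.ndarray, float]:
    """Scale a measure to SD units (of its logs, by default).

    Returns ``(z, sd)`` with z = log(value)/sd; centering is omitted because
    the conditional likelihood is invariant to location shifts.  The SD is
    computed over all subjects supplied (pooled cases + controls).
    """
    values = np.asarray(values, dtype=float)
    if log_transform:
        bad = np.flatnonzero(~(values > 0))
        if bad.size:
            raise ValueError(
                f"log transform requires positive values; offending rows: {bad[:20].tolist()}"
            )
        x = np.log(values)
    else:
        x = values
    sd = float(x.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(x.mean()))):
        raise ValueError("degenerate measure: zero standard deviation")
    return x / sd, sd


def _encode_covariate(series: pd.Series) -> pd.Series:
    """Numeric passthrough; binary indicator for two-level categoricals."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    levels = sorted(x for x in series.dropna().unique() if str(x).lower() != "unknown")
    if len(levels) != 2:
        raise ValueError(
            f"categorical covariate '{series.name}' must have exactly 2 informative levels, got {levels}"
        )
    out = series.map({levels[0]: 0.0, levels[1]: 1.0})
    return out


def clogit_pairs(
    cohort: MatchedCohort,
    exposure: str,
    covariates: Sequence[str] = (),
    log_transform: bool = True,
    standardize: bool = True,
) -> ORResult:
    """1:1 conditional logistic regression for one exposure.

    Fits the conditional likelihood via a no-intercept logistic regression
    on within-pair (case - control) differences, Newton optimization.  Pairs
    with a missing/unknown covariate value in either member are dropped
    whole.  Returns the per-SD odds ratio (per-unit when ``standardize`` is
    off, e.g. for a binary exposure) with a 95% Wald CI and the Az of the
    fitted linear predictor.
    """
    if standardize:
        z, sd = standardize_per_sd(cohort.data[exposure].to_numpy(), log_transform)
    else:
        z = cohort.data[exposure].to_numpy(float)
        if log_transform:
            z = np.log(z)
        sd = 1.0
    work = cohort.data.copy()
    work["_z"] = z
    cols = ["_z"]
    for cov in covariates:
        work[f"_c_{cov}"] = _encode_covariate(work[cov])
        cols.append(f"_c_{cov}")

    # drop pairs with any missing covariate value
    bad_pairs = work.loc[work[cols].isna().any(axis=1), "pair_id"].unique()
    work = work[~work["pair_id"].isin(bad_pairs)]
    if work["pair_id"].nunique() < 2:
        raise ValueError("fewer than 2 complete pairs after exclusions")

    cases = work[work["status"] == "case"].sort_values("pair_id")
    controls = work[work["status"] == "control"].sort_values("pair_id")
    diffs = cases[cols].to_numpy(float) - controls[cols].to_numpy(float)
    if not np.any(diffs[:, 0] != 0):
        # exposure concordant within every pair: no information, beta = 0
        beta, se = 0.0, float("inf")
    else:
        model = sm.Logit(np.ones(len(diffs)), diffs)
        try:
            fit = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except Exception as exc:  # PerfectSeparation or LinAlgError
            raise ValueError(f"conditional logistic fit failed: {exc}") from exc
        if not fit.mle_retvals.get("converged", False):
            raise ValueError("conditional logistic fit did not converge in 100 iterations")
        beta = float(fit.params[0])
        se = float(fit.bse[0])
        if not np.isfinite(beta) or not np.isfinite(se):
            raise ValueError("separation: conditional MLE is unbounded")
        lp = work[cols].to_numpy(float) @ fit.params
        work = work.assign(_lp=lp)

    if np.isfinite(se):
        ci_low, ci_high = np.exp(beta - Z_95 * se), np.exp(beta + Z_95 * se)
        case_scores = work.loc[work["status"] == "case", "_lp"].to_numpy()
        ctrl_scores = work.loc[work["status"] == "control", "_lp"].to_numpy()
        az, az_lo, az_hi, _ = az_discrimination(case_scores, ctrl_scores)
    else:
        ci_low = ci_high = 1.0
        az, az_lo, az_hi = 0.5, 0.5, 0.5
    return ORResult(
        measure_name=exposure,
        sd_used=sd,
        beta=beta,
        se=se,
        or_value=float(np.exp(beta)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        az=az,
        az_ci_low=az_lo,
        az_ci_high=az_hi,
        adjusted=bool(covariates),
    )


def az_discrimination(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> tuple[float, float, float, bool]:
    """Rank-based AUC with a DeLong-type 95% CI.

    Returns ``(az, ci_low, ci_high, degenerate)``.  Ties count one half.  A
    constant predictor gives Az = 0.5 with a degenerate (zero-width) CI,
    flagged via the last element.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("need at least 2 cases and 2 controls")

    # midrank placement structural components
    all_scores = np.concatenate([x, y])
    if np.ptp(all_scores) == 0:
        return 0.5, 0.5, 0.5, True
    r_all = stats.rankdata(all_scores)
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    v10 = (r_all[:m] - r_x) / n  # P(X > Y) + 0.5 P(X = Y), per case
    v01 = 1.0 - (r_all[m:] - r_y) / m  # per control
    az = float(v10.mean())
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = s10 / m + s01 / n
    if var <= 0:
        return az, az, az, True
    half = Z_95 * float(np.sqrt(var))
    return az, max(0.0, az - half), min(1.0, az + half), False


def pearson_r(
    x: np.ndarray, y: np.ndarray, outlier_rule: Optional[str] = "z3"
) -> float:
    """Sample Pearson correlation after excluding outliers on x.

    ``outlier_rule='z3'`` (default) drops points whose x lies more than 3
    SDs from the x mean; ``None`` keeps everything.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.ones(len(x), dtype=bool)
    if outlier_rule == "z3":
        sd = x.std(ddof=1)
        if sd > 0:
            keep = np.abs(x - x.mean()) <= 3 * sd
    elif outlier_rule is not None:
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points after exclusions")
    xs, ys = x[keep], y[keep]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(xs, ys)[0])


def pooled_mean(ns: Sequence[float], means: Sequence[float]) -> float:
    """n-weighted mean of group means."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    return float((ns * means).sum() / ns.sum())


def cohort_summary(
    cohort: MatchedCohort,
    continuous: Sequence[str] = ("bmi",),
    categorical: Sequence[str] = ("ethnicity",),
) -> pd.DataFrame:
    """Population-characteristics table by case-control status.

    Continuous variables get per-group and pooled means/SDs with a Welch
    t-test p-value; categorical variables get per-level counts and relative
    frequencies with a per-level Fisher exact p-value (level vs rest).
    Pooled means are the n-weighted means of the group means.
    """
    cases, controls = cohort.split()
    rows = []
    for var in continuous:
        vc = cases[var].dropna().to_numpy(float)
        vk = controls[var].dropna().to_numpy(float)
        _, p = stats.ttest_ind(vc, vk, equal_var=False)
        rows.append(
            {
                "variable": var,
                "level": "",
                "case_n": len(vc),
                "case_stat": vc.mean(),
                "case_sd": vc.std(ddof=1),
                "control_n": len(vk),
                "control_stat": vk.mean(),
                "control_sd": vk.std(ddof=1),
                "total_n": len(vc) + len(vk),
                "total_stat": pooled_mean([len(vc), len(vk)], [vc.mean(), vk.mean()]),
                "total_sd": np.concatenate([vc, vk]).std(ddof=1),
                "p_value": float(p),
            }
        )
    for var in categorical:
        levels = sorted(cohort.data[var].dropna().unique())
        nc, nk = len(cases), len(controls)
        for lev in levels:
            cc = int((cases[var] == lev).sum())
            kk = int((controls[var] == lev).sum())
            _, p = stats.fisher_exact([[cc, nc - cc], [kk, nk - kk]])
            rows.append(
                {
                    "variable": var,
                    "level": str(lev),
                    "case_n": cc,
                    "case_stat": 100.0 * cc / nc,
                    "case_sd": np.nan,
                    "control_n": kk,
                    "control_stat": 100.0 * kk / nk,
                    "control_sd": np.nan,
                    "total_n": cc + kk,
                    "total_stat": 100.0 * (cc + kk) / (nc + nk),
                    "total_sd": np.nan,
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)
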