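"""Cohort-level statistics: group comparison, scale correlations, outlier refits.

Implements the study's statistical layer over subject-level parameter
sets: two-sample t comparisons of every registry parameter between the
hemiplegia and control groups, Pearson correlations (reported as R^2)
of the 22 correlation parameters against the four stroke severity
scales (FMA lower/upper extremity, MMSE, MBI) with least-squares lines
of scale on parameter, and an outlier-excluded refit that removes the
point with the largest absolute studentized residual.

The t test is Welch's by default (unequal variances) with a pooled
option; p-values are two-sided throughout.  The headline correlation
table is unadjusted at alpha = 0.05, with a Benjamini-Hochberg adjusted
flag carried as an extra column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .gait_parameters import CORRELATION_PARAMETERS, PARAMETER_REGISTRY
from .sensor_model import SubjectRecord

SCALES = ("fma_lex", "fma_uex", "mmse", "mbi")
ALPHA = 0.05


@dataclass
class TTestResult:
    parameter: str
    mean_a: float
    range_a: tuple[float, float]
    n_a: int
    mean_b: float
    range_b: tuple[float, float]
    n_b: int
    t_stat: float
    df: float
    p_two_sided: float


@dataclass
class CorrelationResult:
    parameter: str
    scale: str
    n: int
    r: float
    r_squared: float
    slope: float
    intercept: float
    p_two_sided: float
    excluded_index: Optional[int] = None
    r_squared_excluded: Optional[float] = None


def _clean_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise InputError(f"sample {name} needs >= 2 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"sample {name} contains non-finite values")
    return arr


def two_sample_t(a, b, pooled: bool = False, parameter: str = "") -> TTestResult:
    """Two-sample t test (Welch by default) with group means and ranges.

    Two identical zero-variance samples return t = 0, p = 1 instead of
    the undefined statistic.
    """
    a = _clean_sample(a, "a")
    b = _clean_sample(b, "b")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t_stat, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=pooled)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TTestResult(
        parameter=parameter,
        mean_a=float(a.mean()), range_a=(float(a.min()), float(a.max())), n_a=len(a),
        mean_b=float(b.mean()), range_b=(float(b.min()), float(b.max())), n_b=len(b),
        t_stat=t_stat, df=df, p_two_sided=p,
    )


def compare_groups(records: Sequence[SubjectRecord], pooled: bool = False) -> pd.DataFrame:
    """Patient-vs-control t test for every registry parameter, sorted by p.

    Missing values are dropped per parameter (reported n per group);
    parameters without >= 2 finite values in each group get NaN
    statistics.  Raises if either group is absent.
    """
    patients = [r for r in records if r.group == "patient"]
    controls = [r for r in records if r.group == "control"]
    if len(patients) < 2 or len(controls) < 2:
        raise InputError(
            f"need >= 2 subjects per group, got {len(patients)} patients / "
            f"{len(controls)} controls"
        )
    rows = []
    for name in PARAMETER_REGISTRY:
        a = np.array([getattr(r.params, name) for r in patients], dtype=float)
        b = np.array([getattr(r.params, name) for r in controls], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) >= 2 and len(b) >= 2:
            res = two_sample_t(a, b, pooled=pooled, parameter=name)
            rows.append({
                "parameter": name,
                "mean_patient": res.mean_a, "min_patient": res.range_a[0],
                "max_patient": res.range_a[1], "n_patient": res.n_a,
                "mean_control": res.mean_b, "min_control": res.range_b[0],
                "max_control": res.range_b[1], "n_control": res.n_b,
                "t_stat": res.t_stat, "df": res.df, "p_value": res.p_two_sided,
            })
        else:
            rows.append({"parameter": name, "n_patient": len(a), "n_control": len(b)})
    df = pd.DataFrame(rows)
    return df.sort_values("p_value", na_position="last", kind="mergesort").reset_index(drop=True)


def correlate(x, y, parameter: str = "", scale: str = "") -> CorrelationResult:
    """Pearson correlation of paired values with the y-on-x least-squares line.

    p is two-sided from t = r sqrt((n-2)/(1-r^2)) on n-2 df.  A
    zero-variance input yields NaN markers (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InputError(f"correlation needs >= 3 paired finite values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(parameter, scale, n, math.nan, math.nan,
                                 math.nan, math.nan, math.nan)
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    return CorrelationResult(
        parameter=parameter, scale=scale, n=n, r=r, r_squared=r * r,
        slope=float(fit.slope), intercept=float(fit.intercept),
        p_two_sided=float(fit.pvalue),
    )


def correlate_scales(records: Sequence[SubjectRecord],
                     alpha: float = ALPHA) -> pd.DataFrame:
    """All 22 parameters x 4 scales correlations over the patient group.

    Returns the full 88-row table with an unadjusted significance flag at
    ``alpha`` (mirroring an uncorrected analysis) plus a
    Benjamini-Hochberg adjusted flag as an extra column; sortable by R^2.
    """
    patients = [r for r in records if r.group == "patient" and r.scores is not None]
    if len(patients) < 3:
        raise InputError(f"need >= 3 patients with scores, got {len(patients)}")
    rows = []
    for name in CORRELATION_PARAMETERS:
        x_all = np.array([getattr(r.params, name) for r in patients], dtype=float)
        for scale in SCALES:
            y_all = np.array(
                [getattr(r.scores, scale) if getattr(r.scores, scale) is not None
                 else math.nan for r in patients], dtype=float)
            row = {"parameter": name, "scale": scale.upper()}
            try:
                res = correlate(x_all, y_all, parameter=name, scale=scale)
                row.update({"n": res.n, "r": res.r, "r_squared": res.r_squared,
                            "slope": res.slope, "intercept": res.intercept,
                            "p_value": res.p_two_sided})
            except InputError:
                row.update({"n": int(np.sum(np.isfinite(x_all) & np.isfinite(y_all)))})
            rows.append(row)
    df = pd.DataFrame(rows)
    df["significant"] = df["p_value"] < alpha
    pvals = df["p_value"].to_numpy(dtype=float)
    ok = np.isfinite(pvals)
    adj = np.full(len(df), math.nan)
    if ok.any():
        adj[ok] = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[1]
    df["p_bh"] = adj
    df["significant_bh"] = df["p_bh"] < alpha
    return df.sort_values("r_squared", ascending=False,
                          na_position="last", kind="mergesort").reset_index(drop=True)


def studentized_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Internally studentized residuals of the y-on-x simple regression."""
    n = len(x)
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sxx = np.sum((x - x.mean()) ** 2)
    h = 1.0 / n + (x - x.mean()) ** 2 / sxx
    s2 = np.sum(resid ** 2) / (n - 2)
    denom = np.sqrt(s2 * (1.0 - h))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, resid / denom, 0.0)


def refit_without_outlier(x, y, parameter: str = "", scale: str = "") -> CorrelationResult:
    """Refit the correlation after removing the largest-|studentized-residual| point.

    The exclusion is unconditional (a reporting device, not an outlier
    test): the candidate is the point with maximum absolute internally
    studentized residual from the full fit; both R^2 values and the
    excluded index are reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise InputError(f"outlier refit needs >= 4 paired values, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("outlier refit requires finite values")
    full = correlate(x, y, parameter=parameter, scale=scale)
    idx = int(np.argmax(np.abs(studentized_residuals(x, y))))
    keep = np.ones(len(x), dtype=bool)
    keep[idx] = False
    sub = correlate(x[keep], y[keep], parameter=parameter, scale=scale)
    full.excluded_index = idx
    full.r_squared_excluded = sub.r_squared
    return full
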