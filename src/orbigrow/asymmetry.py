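"""Within-individual right-vs-left orbital asymmetry tests.

Cross-sectional studies have compared the *average* right orbit with the
*average* left orbit using an independent two-sample t-test, which throws
away the pairing and has low power against small systematic asymmetries.
The tests here are within-individual: the paired (dependent) t-test on the
per-subject right-minus-left difference, the one-sample t-test on the
per-subject right/left ratio against one, and an OLS regression of the
per-subject asymmetry on sex with heteroskedasticity-robust (HC1) standard
errors, whose intercept tests the asymmetry at the reference sex.

Subjects with several scans are collapsed to their across-scan mean right
and left volumes by default (one observation per patient, matching the
within-individual estimand); per-scan units are available via
``unit="scan"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AsymmetryResult",
    "paired_difference_test",
    "ratio_test",
    "robust_regression",
    "collapse_bilateral",
    "asymmetry_from_records",
]


@dataclass
class AsymmetryResult:
    """Result of one right-vs-left test."""

    test_kind: str                      # "difference" | "ratio" | "regression"
    n: int
    mean_diff: float                    # mean(right - left), mm^3
    mean_ratio: float                   # mean(right / left)
    t_stat: float
    p_value: float
    df: float
    coefficients: Optional[Dict[str, Dict[str, float]]] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 subjects")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _one_sample_t(x: np.ndarray, what: str):
    """Two-sided one-sample t against 0; degenerate zero-spread input gives
    t = +/-inf (p = 0) for a nonzero mean and raises for an all-zero effect."""
    if np.allclose(x.std(ddof=1), 0.0):
        if np.allclose(x.mean(), 0.0):
            raise ValueError(f"zero variance of {what}; t statistic undefined")
        return math.copysign(math.inf, x.mean()), 0.0
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p)


def _validate_sides(right, left):
    r = np.asarray(right, dtype=float)
    l = np.asarray(left, dtype=float)
    if r.shape != l.shape or r.ndim != 1 or r.size < 2:
        raise ValueError("right and left must be equal-length 1-D vectors, n >= 2")
    return r, l


def paired_difference_test(
    right: Sequence[float], left: Sequence[float]
) -> AsymmetryResult:
    """Dependent t-test: is the mean within-subject (right - left) zero?"""
    r, l = _validate_sides(right, left)
    d = r - l
    t, p = _one_sample_t(d, "differences")
    return AsymmetryResult(
        test_kind="difference",
        n=d.size,
        mean_diff=float(d.mean()),
        mean_ratio=float((r / l).mean()),
        t_stat=float(t),
        p_value=float(p),
        df=float(d.size - 1),
    )


def ratio_test(right: Sequence[float], left: Sequence[float]) -> AsymmetryResult:
    """One-sample t-test: is the mean within-subject right/left ratio one?"""
    r, l = _validate_sides(right, left)
    if np.any(l <= 0) or np.any(r <= 0):
        raise ValueError("volumes must be strictly positive")
    x = r / l - 1.0
    t, p = _one_sample_t(x, "ratios")
    return AsymmetryResult(
        test_kind="ratio",
        n=x.size,
        mean_diff=float((r - l).mean()),
        mean_ratio=float((r / l).mean()),
        t_stat=float(t),
        p_value=float(p),
        df=float(x.size - 1),
    )


def robust_regression(
    outcome: Sequence[float], sex: Sequence[str | int]
) -> AsymmetryResult:
    """OLS of a per-subject asymmetry on sex with HC1-robust standard errors.

    ``outcome`` is the per-subject difference (mm^3) or ratio - 1; ``sex``
    is coded F = 0 (reference), M = 1 (strings "F"/"M" accepted).  The
    reported t/p test the intercept (asymmetry at the reference sex); both
    coefficients with robust SEs are returned in ``coefficients``.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    s = np.asarray(sex)
    if s.dtype.kind in "UO":
        s = np.where(s == "M", 1.0, 0.0)
    s = s.astype(float)
    if y.ndim != 1 or y.shape != s.shape or y.size < 3:
        raise ValueError("outcome and sex must be equal-length 1-D vectors, n >= 3")
    names = ["intercept", "male"]
    if np.unique(s).size < 2:
        warnings.warn("sex covariate is constant; dropped from the regression")
        X = np.ones((y.size, 1))
        names = ["intercept"]
    else:
        X = np.column_stack([np.ones(y.size), s])
    res = sm.OLS(y, X).fit(cov_type="HC1")
    coefs = {}
    for i, name in enumerate(names):
        coef, se = float(res.params[i]), float(res.bse[i])
        t, p = float(res.tvalues[i]), float(res.pvalues[i])
        if se == 0.0:  # degenerate all-constant outcome: 0/0 t statistic
            t = 0.0 if coef == 0.0 else math.copysign(math.inf, coef)
            p = 1.0 if coef == 0.0 else 0.0
        coefs[name] = {"coef": coef, "se": se, "t": t, "p": p}
    return AsymmetryResult(
        test_kind="regression",
        n=y.size,
        mean_diff=float(y.mean()),
        mean_ratio=float(1.0 + y.mean()),
        t_stat=coefs["intercept"]["t"],
        p_value=coefs["intercept"]["p"],
        df=float(y.size - X.shape[1]),
        coefficients=coefs,
    )


def collapse_bilateral(records, unit: str = "patient") -> pd.DataFrame:
    """Per-unit right and left volumes from scan records.

    ``unit="patient"`` (default) averages each patient's scans so every
    patient contributes one right/left pair; ``unit="scan"`` keeps one row
    per scan.  Returns columns ``patient_id, sex, right, left``.
    """
    from .cohort import ScanRecord, records_to_frame

    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    frame = records.rename(
        columns={"right_volume_mm3": "right", "left_volume_mm3": "left"}
    )
    if unit == "scan":
        return frame[["patient_id", "sex", "right", "left"]].reset_index(drop=True)
    if unit != "patient":
        raise ValueError("unit must be 'patient' or 'scan'")
    return (
        frame.groupby(["patient_id", "sex"], sort=True)[["right", "left"]]
        .mean()
        .reset_index()
    )


def asymmetry_from_records(
    records, test: str = "difference", unit: str = "patient"
) -> AsymmetryResult:
    """Run one asymmetry test on a scan table or record list."""
    collapsed = collapse_bilateral(records, unit=unit)
    r = collapsed["right"].to_numpy()
    l = collapsed["left"].to_numpy()
    if test == "difference":
        return paired_difference_test(r, l)
    if test == "ratio":
        return ratio_test(r, l)
    if test == "regression":
        return robust_regression(r / l - 1.0, collapsed["sex"].to_numpy())
    raise ValueError("test must be 'difference', 'ratio' or 'regression'")
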