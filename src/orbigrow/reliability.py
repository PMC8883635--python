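"""Measurement reliability: intraclass correlation and Bland-Altman agreement.

Repeated volume measurements (the same operator re-measuring after a washout
period, or two operators measuring independently) are summarized two ways:

- the intraclass correlation coefficient (ICC) from the two-way ANOVA
  mean-squares decomposition — by default the two-way random-effects,
  absolute-agreement, single-measurement form, the standard convention for
  operator-agreement designs; consistency (two-way mixed) and one-way
  random forms are selectable and labeled in the result;
- Bland-Altman bias and 95% limits of agreement
  (bias +/- 1.96 * SD of the paired differences).

For two repeats the Pearson correlation ("interclass correlation" in the
older sense) is reported alongside the ICC for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReliabilityResult",
    "icc",
    "bland_altman",
    "long_to_wide",
    "plot_bland_altman",
]

_ICC_MODELS = ("two_way_absolute", "two_way_consistency", "one_way")


@dataclass
class ReliabilityResult:
    """Reliability summary; ICC fields or agreement fields may be unset
    depending on which statistic produced it."""

    n: int
    icc: Optional[float] = None
    icc_model: Optional[str] = None
    pearson_r: Optional[float] = None
    bias: Optional[float] = None
    sd_diff: Optional[float] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 subjects")
        if self.bias is not None and not (
            self.loa_low <= self.bias <= self.loa_high
        ):
            raise ValueError("limits of agreement must bracket the bias")


def long_to_wide(
    frame: pd.DataFrame, design: str = "inter"
) -> np.ndarray:
    """Pivot a long reliability table to an orbits x repeats array.

    ``design="inter"`` treats operators as repeats (one replicate each);
    ``design="intra"`` treats replicates of a single operator as repeats.
    Expects columns ``orbit_id, operator_id, replicate_id, volume_mm3``.
    """
    required = {"orbit_id", "operator_id", "replicate_id", "volume_mm3"}
    if not required <= set(frame.columns):
        raise ValueError(f"reliability table needs columns {sorted(required)}")
    if design == "inter":
        wide = frame.pivot_table(
            index="orbit_id", columns="operator_id", values="volume_mm3"
        )
    elif design == "intra":
        ops = frame["operator_id"].unique()
        sub = frame[frame["operator_id"] == ops[0]]
        wide = sub.pivot_table(
            index="orbit_id", columns="replicate_id", values="volume_mm3"
        )
    else:
        raise ValueError("design must be 'intra' or 'inter'")
    if wide.isna().any().any():
        raise ValueError("missing cells in the reliability design")
    return wide.to_numpy()


def icc(
    measurements: np.ndarray | pd.DataFrame, model: str = "two_way_absolute"
) -> ReliabilityResult:
    """Single-measurement ICC of an orbits x repeats table.

    Mean squares of the two-way layout (n targets, k repeats): MSR between
    targets, MSC between repeats, MSE residual.  The conventions are

    - ``two_way_absolute`` (default, "ICC(2,1)"):
      ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``
    - ``two_way_consistency`` ("ICC(3,1)"):
      ``(MSR - MSE) / (MSR + (k-1) MSE)``
    - ``one_way`` ("ICC(1,1)"):
      ``(MSR - MSW) / (MSR + (k-1) MSW)`` with the within-target mean
      square ``MSW`` pooling repeat and residual variation.
    """
    if model not in _ICC_MODELS:
        raise ValueError(f"model must be one of {_ICC_MODELS}")
    X = np.asarray(
        measurements.to_numpy() if isinstance(measurements, pd.DataFrame)
        else measurements,
        dtype=float,
    )
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 2 targets, k >= 2 repeats")
    if np.isnan(X).any():
        raise ValueError("missing cells are not supported")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("zero total variance; ICC undefined")
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "two_way_absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "two_way_consistency":
        denom = msr + (k - 1) * mse
    else:
        msw = (ss_cols + ss_err) / (n * (k - 1))
        mse = msw
        denom = msr + (k - 1) * msw
    value = (msr - mse) / denom if denom != 0 else float("nan")
    pearson = float(np.corrcoef(X[:, 0], X[:, 1])[0, 1]) if k == 2 else None
    return ReliabilityResult(n=n, icc=float(value), icc_model=model, pearson_r=pearson)


def bland_altman(m1: Sequence[float], m2: Sequence[float]) -> ReliabilityResult:
    """Bias and 95% limits of agreement of two paired measurement series."""
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("m1 and m2 must be equal-length 1-D vectors, n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return ReliabilityResult(
        n=a.size,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=float(np.corrcoef(a, b)[0, 1]) if a.size > 2 else None,
    )


def plot_bland_altman(m1: Sequence[float], m2: Sequence[float], ax=None):
    """Difference-vs-mean scatter with bias and limits-of-agreement lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(m1, m2)
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2.0, a - b, s=18, alpha=0.8)
    for yv, style, label in (
        (res.bias, "-", "bias"),
        (res.loa_low, "--", "-1.96 SD"),
        (res.loa_high, "--", "+1.96 SD"),
    ):
        ax.axhline(yv, ls=style, color="grey")
        ax.annotate(label, xy=(0.99, yv), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of measurements (mm$^3$)")
    ax.set_ylabel("difference (mm$^3$)")
    return ax
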