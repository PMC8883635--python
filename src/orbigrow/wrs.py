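"""Weighted repeat-scan (WRS) growth index.

The estimator treats each patient like a repeatedly "sold" asset in a
repeat-sales price index: the response is the within-patient log-volume
growth between consecutive scans, which differences out every time-invariant
patient characteristic.  Estimation is three-stage:

1. **Stage 1 (OLS).**  Regress pair growth on age-class indicator contrasts
   ``D_{i,l}`` (+1 if the pair's later class k equals l, -1 if the earlier
   class j equals l, 0 otherwise; the base class's column is omitted, fixing
   its coefficient at zero).  No intercept.  The coefficient ``gamma_l`` is
   the cumulative log-volume index of class l relative to the base class.

2. **Stage 2 (variance model).**  Regress the squared stage-1 residuals on
   the pair interval (k - j, years) with an intercept:
   ``e^2 = alpha + beta * (k - j)``.  Under the generative model with i.i.d.
   measurement noise (variance s_e^2) and a random-walk drift (variance
   s_w^2 per year), alpha estimates 2*s_e^2 and beta estimates s_w^2.

3. **Stage 3 (WLS).**  Re-estimate stage 1 weighting each pair by the
   inverse of its fitted stage-2 variance (rows divided by the square root
   of the fitted value): long intervals, which are noisier under the drift
   model, are down-weighted.

Standard errors are cluster-robust by patient (sandwich estimator on the
weighted regression), with a Stata-style small-sample factor
``G/(G-1) * (N-1)/(N-K)`` and two-sided p-values from the t distribution
with G - 1 degrees of freedom, G the number of patients contributing pairs.

The log index converts to volume levels by exponentiating and multiplying
by the observed mean volume in the base age class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .panel import build_growth_pairs, build_panel

__all__ = [
    "DesignMatrix",
    "WRSFit",
    "VolumeIndex",
    "WRSResult",
    "build_design_matrix",
    "fit_stage1_ols",
    "fit_stage2_variance",
    "fit_stage3_wls",
    "clustered_se",
    "index_to_levels",
    "fit_wrs",
    "fit_wrs_index",
    "plot_index_vs_average",
]


@dataclass
class DesignMatrix:
    """Repeat-scan contrast design.

    ``X[i, c] = +1`` if pair i's later age class equals ``ages[c]``, ``-1``
    if its earlier class does, else 0; the base class has no column.  Row
    order matches the pair table; ``patient_ids`` carries the clustering
    variable.
    """

    X: np.ndarray
    ages: List[int]
    base_age: int
    patient_ids: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


@dataclass
class WRSFit:
    """Three-stage fit: index coefficients, variance model, inference."""

    base_age: int
    ages: List[int]                      # non-base classes, sorted
    gamma: Dict[int, float]              # includes base -> 0.0
    se: Dict[int, float]                 # clustered, non-base classes
    p_values: Dict[int, float]           # two-sided, t with G-1 df
    t_stats: Dict[int, float]
    alpha: float                         # variance-model intercept
    beta: float                          # variance-model slope per year
    stage1_gamma: Dict[int, float]
    stage1_residuals: np.ndarray
    fitted_variance: np.ndarray          # floored stage-2 fitted values
    weights: np.ndarray                  # 1 / fitted variance (or literal)
    r_squared: float                     # uncentered, weighted regression
    n_obs: int
    n_clusters: int
    cov: Optional[np.ndarray] = None


@dataclass
class VolumeIndex:
    """Age-class volume levels (mm^3) anchored at the base class mean."""

    base_age: int
    base_mean_volume: float
    levels: Dict[int, float]


@dataclass
class WRSResult:
    """Full pipeline output: fit, levels, and per-class simple averages."""

    fit: WRSFit
    index: VolumeIndex
    simple_averages: pd.DataFrame        # age_class, mean_volume, n_scans
    subgroup: str = "all"


def build_design_matrix(pairs: pd.DataFrame, base_age: int) -> DesignMatrix:
    """Assemble the +1/-1 contrast matrix from a pair table.

    Raises if any observed age class is not connected to the base class
    through the pair graph — its coefficient would be unidentified.
    """
    if len(pairs) == 0:
        raise ValueError("no growth pairs")
    observed = sorted(set(pairs["j"].astype(int)) | set(pairs["k"].astype(int)))
    # connectivity of the age-class graph from the base class
    adjacency: Dict[int, set] = {a: set() for a in observed}
    for j, k in zip(pairs["j"].astype(int), pairs["k"].astype(int)):
        if j == k:
            raise ValueError("pair with equal age classes (j == k)")
        adjacency[j].add(k)
        adjacency[k].add(j)
    reachable = set()
    frontier = [base_age] if base_age in adjacency else []
    while frontier:
        node = frontier.pop()
        if node in reachable:
            continue
        reachable.add(node)
        frontier.extend(adjacency[node] - reachable)
    unreachable = [a for a in observed if a not in reachable]
    if unreachable:
        raise ValueError(
            f"age classes {unreachable} are not connected to base age "
            f"{base_age} through any pair; their coefficients are unidentified"
        )
    ages = [a for a in observed if a != base_age]
    col = {a: c for c, a in enumerate(ages)}
    X = np.zeros((len(pairs), len(ages)))
    for i, (j, k) in enumerate(zip(pairs["j"].astype(int), pairs["k"].astype(int))):
        if k != base_age:
            X[i, col[k]] = 1.0
        if j != base_age:
            X[i, col[j]] = -1.0
    return DesignMatrix(
        X=X,
        ages=ages,
        base_age=base_age,
        patient_ids=pairs["patient_id"].to_numpy(),
    )


def _lstsq_full_rank(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; check age-class connectivity"
        )
    return coef


def fit_stage1_ols(
    design: DesignMatrix, growth: Sequence[float]
) -> Tuple[Dict[int, float], np.ndarray]:
    """Stage-1 OLS (no intercept): coefficients and residuals."""
    y = np.asarray(growth, dtype=float)
    if y.shape[0] != design.n_obs:
        raise ValueError("growth length does not match design rows")
    coef = _lstsq_full_rank(design.X, y)
    residuals = y - design.X @ coef
    gamma = {a: float(c) for a, c in zip(design.ages, coef)}
    gamma[design.base_age] = 0.0
    return gamma, residuals


def fit_stage2_variance(
    residuals: Sequence[float], intervals: Sequence[float]
) -> Tuple[float, float, np.ndarray]:
    """Stage-2 regression of squared residuals on the pair interval.

    Returns ``(alpha, beta, fitted_sq)``.  With fewer than two distinct
    interval values the slope is unidentified; the fit degrades to
    intercept-only (beta = 0) with a warning.
    """
    e2 = np.asarray(residuals, dtype=float) ** 2
    d = np.asarray(intervals, dtype=float)
    if e2.shape != d.shape or e2.size < 2:
        raise ValueError("need >= 2 residuals with matching intervals")
    if np.unique(d).size < 2:
        warnings.warn(
            "all pair intervals identical; variance model degrades to "
            "intercept-only (beta = 0)",
            stacklevel=2,
        )
        alpha = float(e2.mean())
        return alpha, 0.0, np.full_like(e2, alpha)
    Z = np.column_stack([np.ones_like(d), d])
    ab = _lstsq_full_rank(Z, e2)
    fitted = Z @ ab
    return float(ab[0]), float(ab[1]), fitted


def _floor_fitted_variance(fitted_sq: np.ndarray) -> np.ndarray:
    """Floor fitted variances so weights stay finite.

    The linear variance model can go non-positive at short intervals; the
    floor is ``max(1e-10, 1e-3 * median(fitted))``.
    """
    floor = max(1e-10, 1e-3 * float(np.median(fitted_sq)))
    return np.maximum(fitted_sq, floor)


def fit_stage3_wls(
    design: DesignMatrix,
    growth: Sequence[float],
    fitted_sq: Sequence[float],
    weight_mode: str = "inverse_variance",
) -> Tuple[Dict[int, float], np.ndarray, np.ndarray, np.ndarray, float]:
    """Stage-3 weighted fit.

    ``weight_mode="inverse_variance"`` (default) divides each row and its
    response by the square root of the (floored) fitted stage-2 variance,
    i.e. WLS with weight 1/variance — noisy long-interval pairs are
    down-weighted.  ``"literal"`` instead multiplies by that square root,
    the verbatim reading of "the square root of the fitted values are the
    regression weights"; it is exposed for sensitivity analysis only.

    Returns ``(gamma, weights, weighted_residuals, fitted_variance,
    r_squared)`` where ``r_squared`` is the uncentered R^2 of the weighted
    no-intercept regression.
    """
    if weight_mode not in ("inverse_variance", "literal"):
        raise ValueError("weight_mode must be 'inverse_variance' or 'literal'")
    y = np.asarray(growth, dtype=float)
    fv = _floor_fitted_variance(np.asarray(fitted_sq, dtype=float))
    scale = 1.0 / np.sqrt(fv) if weight_mode == "inverse_variance" else np.sqrt(fv)
    Xw = design.X * scale[:, None]
    yw = y * scale
    coef = _lstsq_full_rank(Xw, yw)
    resid_w = yw - Xw @ coef
    ss_res = float(resid_w @ resid_w)
    ss_tot = float(yw @ yw)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    gamma = {a: float(c) for a, c in zip(design.ages, coef)}
    gamma[design.base_age] = 0.0
    return gamma, scale**2, resid_w, fv, r2


def clustered_se(
    Xw: np.ndarray,
    resid_w: np.ndarray,
    cluster_ids: Sequence,
    small_sample: str = "stata",
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Cluster-robust sandwich covariance on a (weighted) regression.

    ``V = c * (X'X)^-1 [ sum_g (X_g' u_g)(X_g' u_g)' ] (X'X)^-1`` with
    ``c = G/(G-1) * (N-1)/(N-K)`` (``small_sample="stata"``) or ``c = 1``
    (``"none"``).  Returns ``(se, cov, n_clusters)``.
    """
    if small_sample not in ("stata", "none"):
        raise ValueError("small_sample must be 'stata' or 'none'")
    ids = np.asarray(cluster_ids)
    n, k = Xw.shape
    groups = pd.unique(ids)
    G = len(groups)
    if G < 2:
        raise ValueError("clustered standard errors need >= 2 clusters")
    bread = np.linalg.inv(Xw.T @ Xw)
    meat = np.zeros((k, k))
    for g in groups:
        mask = ids == g
        s = Xw[mask].T @ resid_w[mask]
        meat += np.outer(s, s)
    c = 1.0
    if small_sample == "stata":
        c = (G / (G - 1)) * ((n - 1) / (n - k))
    cov = c * bread @ meat @ bread
    # the sandwich is PSD; clip tiny negative rounding on the diagonal
    return np.sqrt(np.clip(np.diag(cov), 0.0, None)), cov, G


def index_to_levels(fit: WRSFit, base_mean_volume: float) -> VolumeIndex:
    """Convert the log index to volume levels (mm^3).

    ``levels[l] = base_mean_volume * exp(gamma_l)``; the base class maps to
    ``base_mean_volume`` exactly.
    """
    if base_mean_volume <= 0:
        raise ValueError("base_mean_volume must be positive")
    levels = {
        a: (base_mean_volume if a == fit.base_age else base_mean_volume * math.exp(g))
        for a, g in sorted(fit.gamma.items())
    }
    levels[fit.base_age] = base_mean_volume
    return VolumeIndex(
        base_age=fit.base_age, base_mean_volume=base_mean_volume, levels=levels
    )


def fit_wrs(
    pairs: pd.DataFrame,
    base_age: int = 12,
    weight_mode: str = "inverse_variance",
    small_sample: str = "stata",
) -> WRSFit:
    """Run the three estimation stages plus clustered inference on a pair table."""
    design = build_design_matrix(pairs, base_age)
    growth = pairs["growth"].to_numpy(dtype=float)
    intervals = pairs["interval"].to_numpy(dtype=float)
    stage1_gamma, stage1_resid = fit_stage1_ols(design, growth)
    alpha, beta, fitted_sq = fit_stage2_variance(stage1_resid, intervals)
    gamma, weights, resid_w, fv, r2 = fit_stage3_wls(
        design, growth, fitted_sq, weight_mode=weight_mode
    )
    scale = np.sqrt(weights)
    Xw = design.X * scale[:, None]
    se_vec, cov, G = clustered_se(
        Xw, resid_w, design.patient_ids, small_sample=small_sample
    )
    se = {a: float(s) for a, s in zip(design.ages, se_vec)}
    t_stats = {a: gamma[a] / se[a] for a in design.ages}
    dof = G - 1
    p_values = {
        a: float(2.0 * stats.t.sf(abs(t), dof)) for a, t in t_stats.items()
    }
    return WRSFit(
        base_age=base_age,
        ages=design.ages,
        gamma=gamma,
        se=se,
        p_values=p_values,
        t_stats=t_stats,
        alpha=alpha,
        beta=beta,
        stage1_gamma=stage1_gamma,
        stage1_residuals=stage1_resid,
        fitted_variance=fv,
        weights=weights,
        r_squared=r2,
        n_obs=design.n_obs,
        n_clusters=G,
        cov=cov,
    )


def fit_wrs_index(
    records,
    base_age: int = 12,
    subgroup: str = "all",
    weight_mode: str = "inverse_variance",
    small_sample: str = "stata",
) -> WRSResult:
    """Full pipeline: scans -> panel -> pairs -> three-stage fit -> levels.

    ``records`` may be a list of :class:`~orbigrow.cohort.ScanRecord`, a raw
    scan frame, or an already-built panel frame (with an ``age_class``
    column).  ``subgroup`` restricts to one sex (``"F"``/``"M"``) before
    pair construction.  The level index is anchored at the mean panel volume
    of the base age class; per-class simple averages are returned alongside
    for index-vs-average comparisons.
    """
    if isinstance(records, pd.DataFrame) and "age_class" in records.columns:
        panel = records.copy()
    else:
        panel = build_panel(records)
    if subgroup not in ("all", "F", "M"):
        raise ValueError("subgroup must be 'all', 'F' or 'M'")
    if subgroup != "all":
        if "sex" not in panel.columns:
            raise ValueError("panel has no sex column; cannot filter subgroup")
        panel = panel[panel["sex"] == subgroup]
    if len(panel) == 0:
        raise ValueError(f"no observations in subgroup {subgroup!r}")
    pairs = build_growth_pairs(panel)
    fit = fit_wrs(
        pairs, base_age=base_age, weight_mode=weight_mode, small_sample=small_sample
    )
    at_base = panel.loc[panel["age_class"] == base_age, "mean_volume"]
    if len(at_base) == 0:
        raise ValueError(
            f"no observations at base age {base_age}; choose a different base"
        )
    index = index_to_levels(fit, float(at_base.mean()))
    simple = (
        panel.groupby("age_class")["mean_volume"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_volume", "size": "n_scans"})
    )
    return WRSResult(fit=fit, index=index, simple_averages=simple, subgroup=subgroup)


def plot_index_vs_average(result: WRSResult, ax=None):
    """Index level curve against per-class simple averages (one panel)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ages = sorted(result.index.levels)
    ax.plot(
        ages,
        [result.index.levels[a] for a in ages],
        "o-",
        label="repeat-scan index",
    )
    ax.plot(
        result.simple_averages["age_class"],
        result.simple_averages["mean_volume"],
        "s--",
        label="simple average",
    )
    ax.axvline(result.index.base_age, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("age class (years)")
    ax.set_ylabel("orbital volume (mm$^3$)")
    ax.set_title(f"subgroup: {result.subgroup}")
    ax.legend()
    return ax
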