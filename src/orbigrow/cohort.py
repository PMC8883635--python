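"""Synthetic serial-scan cohort generation.

Real serial CBCT volume panels are irregular: patients contribute different
numbers of scans at clinically driven (hence unevenly spaced) ages.  This
module simulates scan panels with exactly that structure so that the
repeat-scan index estimator, the asymmetry tests and the reliability
statistics can all be exercised and validated without access to patient data.

The generative model for the log volume of one orbital side at exact age
``t`` (years) of patient ``i`` is

    ln V_side(t) = ln(V_base) + mu(t) + u_i + W_i(t) +/- delta/2 + e

where ``mu`` is an age-indexed mean log-volume curve anchored at 0 in the
base age class, ``u_i`` is a time-invariant individual effect
(``Normal(0, sd_individual^2)``), ``W_i`` is a Gaussian random walk whose
increment variance grows linearly with elapsed time
(``Var[W(t2) - W(t1)] = sd_walk_per_year^2 * (t2 - t1)``), ``delta`` is the
mean ln(right/left) bilateral asymmetry (+delta/2 on the right side, -delta/2
on the left, so the bilateral average is unbiased for ``mu``), and ``e`` is
i.i.d. measurement noise per scan per side
(``Normal(0, sd_measurement^2)``).

The individual effect cancels within repeat-scan pairs; the walk and the
measurement noise together produce the interval-dependent pair-residual
variance ``2*sd_measurement^2 + sd_walk_per_year^2 * interval`` that the
second estimation stage of the index is designed to model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ScanRecord",
    "POOLED_GROWTH_SCHEDULE",
    "FEMALE_GROWTH_SCHEDULE",
    "MALE_GROWTH_SCHEDULE",
    "replicate_study_structure",
    "simulate_cohort",
    "simulate_reliability_measurements",
    "records_to_frame",
    "frame_to_records",
    "write_scan_csv",
    "read_scan_csv",
]

#: Published pooled age-class log-volume offsets (base class 12 fixed at 0).
#: Used as the default "true" growth schedule for simulation.
POOLED_GROWTH_SCHEDULE: Dict[int, float] = {
    7: -0.0519,
    8: -0.103,
    9: -0.0678,
    10: -0.0336,
    11: -0.0489,
    12: 0.0,
    13: -0.00591,
    14: 0.0457,
    15: 0.0661,
    16: 0.0691,
    17: 0.0784,
    18: 0.0820,
}

#: Female-subsample schedule (same convention).
FEMALE_GROWTH_SCHEDULE: Dict[int, float] = {
    7: -0.0609,
    8: -0.0908,
    9: -0.0522,
    10: 0.0180,
    11: -0.0156,
    12: 0.0,
    13: 0.0341,
    14: 0.0439,
    15: 0.0621,
    16: 0.0609,
    17: 0.0650,
    18: 0.0712,
}

#: Male-subsample schedule (same convention).
MALE_GROWTH_SCHEDULE: Dict[int, float] = {
    7: -0.0586,
    8: -0.136,
    9: -0.0686,
    10: -0.0724,
    11: -0.0927,
    12: 0.0,
    13: -0.0510,
    14: 0.0529,
    15: 0.0559,
    16: 0.0457,
    17: 0.117,
    18: 0.106,
}

DAYS_PER_YEAR = 365.25


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScanRecord:
    """One scan of one patient: both orbital volumes at an exact age."""

    patient_id: str
    sex: str
    age_days: int
    left_volume: float
    right_volume: float
    operator_id: Optional[str] = None
    replicate_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age_days <= 0:
            raise ValueError("age_days must be positive")
        if self.left_volume <= 0 or self.right_volume <= 0:
            raise ValueError("volumes must be strictly positive")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_patients_by_scan_count
        Map scans-per-patient -> number of patients with that many scans.
    sex_counts
        Map ``{"M": ..., "F": ...}`` of patient counts by sex.
    age_range
        ``(min_years, max_years)`` window for exact scan ages.
    min_interval_days
        Minimum elapsed time between consecutive scans of one patient.
    growth_schedule
        Integer age class -> true log-volume offset from the base class.
        The base class must map to 0.
    base_age
        Age class whose mean volume anchors the level index.
    base_mean_volume
        Mean orbital volume (mm^3) at the base age.
    sd_individual
        SD of the time-invariant individual log-volume effect.
    sd_walk_per_year
        Random-walk drift parameter: the walk's increment variance over an
        interval of ``d`` years is ``sd_walk_per_year**2 * d``.
    sd_measurement
        SD of i.i.d. log-scale measurement noise, per scan per side.
    asymmetry_log_ratio
        Mean of ln(right/left); entered as +/- half on each side.
    age_placement
        ``"snap"`` (default): exact ages snap to integer age-class boundaries,
        so the discrete schedule is exactly the estimand of the class-based
        index. ``"continuous"``: exact ages drawn uniformly within each
        patient's feasible window; the mean curve is then evaluated by linear
        interpolation between integer-age schedule values.
    sex_by_scan_count
        Optional map scan-count -> {sex: patient count} pinning down which
        patients of each scan count are of each sex.  When omitted, female
        patients are assigned first in descending order of scan count.
    seed
        Default seed used when :func:`simulate_cohort` is called without one.
    """

    n_patients_by_scan_count: Dict[int, int]
    sex_counts: Dict[str, int]
    age_range: Tuple[float, float]
    min_interval_days: int = 365
    growth_schedule: Dict[int, float] = field(
        default_factory=lambda: dict(POOLED_GROWTH_SCHEDULE)
    )
    base_age: int = 12
    base_mean_volume: float = 22000.0
    sd_individual: float = 0.05
    sd_walk_per_year: float = 0.02
    sd_measurement: float = 0.01
    asymmetry_log_ratio: float = 0.005
    age_placement: str = "snap"
    sex_by_scan_count: Optional[Dict[int, Dict[str, int]]] = None
    seed: int = 0

    def validate(self) -> None:
        if not self.n_patients_by_scan_count:
            raise ValueError("n_patients_by_scan_count is empty")
        for m, n in self.n_patients_by_scan_count.items():
            if m < 1:
                raise ValueError(f"scans-per-patient must be >= 1, got {m}")
            if n < 0:
                raise ValueError("patient counts must be >= 0")
        if set(self.sex_counts) - {"M", "F"}:
            raise ValueError("sex_counts keys must be 'M'/'F'")
        if any(v < 0 for v in self.sex_counts.values()):
            raise ValueError("sex counts must be >= 0")
        if sum(self.sex_counts.values()) != self.n_patients:
            raise ValueError(
                "sex_counts must sum to the total patient count "
                f"({sum(self.sex_counts.values())} != {self.n_patients})"
            )
        if self.min_interval_days < 1:
            raise ValueError("min_interval_days must be >= 1")
        for sd in (self.sd_individual, self.sd_walk_per_year, self.sd_measurement):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if self.base_mean_volume <= 0:
            raise ValueError("base_mean_volume must be positive")
        if self.base_age not in self.growth_schedule:
            raise ValueError("base_age must be a key of growth_schedule")
        if self.growth_schedule[self.base_age] != 0.0:
            raise ValueError("growth_schedule[base_age] must be 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        keys = sorted(self.growth_schedule)
        if _round_half_up(lo) < keys[0] or _round_half_up(hi) > keys[-1]:
            raise ValueError(
                "age_range must round into the growth_schedule's age classes"
            )
        if self.age_placement not in ("snap", "continuous"):
            raise ValueError("age_placement must be 'snap' or 'continuous'")
        if self.sex_by_scan_count is not None:
            for m, bysex in self.sex_by_scan_count.items():
                if sum(bysex.values()) != self.n_patients_by_scan_count.get(m, 0):
                    raise ValueError(
                        f"sex_by_scan_count[{m}] does not sum to the patient count"
                    )
            for sex in ("M", "F"):
                tot = sum(b.get(sex, 0) for b in self.sex_by_scan_count.values())
                if tot != self.sex_counts.get(sex, 0):
                    raise ValueError(
                        f"sex_by_scan_count totals disagree with sex_counts for {sex}"
                    )

    @property
    def n_patients(self) -> int:
        return sum(self.n_patients_by_scan_count.values())

    @property
    def n_scans(self) -> int:
        return sum(m * n for m, n in self.n_patients_by_scan_count.items())

    def mean_log_curve(self, age_years: np.ndarray | float) -> np.ndarray | float:
        """Mean log-volume offset mu(t), linearly interpolated between the
        integer-age schedule values and clamped outside their range."""
        keys = np.array(sorted(self.growth_schedule), dtype=float)
        vals = np.array([self.growth_schedule[int(k)] for k in keys])
        return np.interp(age_years, keys, vals)


def replicate_study_structure() -> CohortConfig:
    """Preset matching the study cohort the estimator was developed for.

    65 patients (24 M, 41 F), ages ~6.5-18.5 years, 52/10/3 patients with
    2/3/4 serial scans (146 scans, 292 orbits, 81 consecutive pairs), and the
    published pooled age-class schedule as simulation truth.

    The per-sex scan-count mix {4 scans: 3 F; 3 scans: 7 F + 3 M;
    2 scans: 31 F + 21 M} reproduces the study's per-sex scan totals
    (95 female / 51 male) and per-sex pair counts (54 / 27) exactly.
    """
    return CohortConfig(
        n_patients_by_scan_count={2: 52, 3: 10, 4: 3},
        sex_counts={"M": 24, "F": 41},
        age_range=(6.5, 18.49),
        min_interval_days=365,
        growth_schedule=dict(POOLED_GROWTH_SCHEDULE),
        base_age=12,
        base_mean_volume=22000.0,
        sex_by_scan_count={
            4: {"F": 3, "M": 0},
            3: {"F": 7, "M": 3},
            2: {"F": 31, "M": 21},
        },
    )


def _patient_roster(config: CohortConfig) -> List[Tuple[str, str, int]]:
    """Deterministic (patient_id, sex, n_scans) roster."""
    roster: List[Tuple[str, str, int]] = []
    counts = dict(config.sex_counts)
    scan_counts = sorted(config.n_patients_by_scan_count, reverse=True)
    if config.sex_by_scan_count is not None:
        plan = {
            m: dict(config.sex_by_scan_count.get(m, {}))
            for m in scan_counts
        }
    else:
        # females first, descending scan count
        plan = {}
        remaining_f = counts.get("F", 0)
        for m in scan_counts:
            n = config.n_patients_by_scan_count[m]
            nf = min(n, remaining_f)
            remaining_f -= nf
            plan[m] = {"F": nf, "M": n - nf}
    idx = 1
    for m in scan_counts:
        for sex in ("F", "M"):
            for _ in range(plan[m].get(sex, 0)):
                roster.append((f"P{idx:03d}", sex, m))
                idx += 1
    return roster


def _draw_scan_ages(
    config: CohortConfig, n_scans: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Scan ages for one patient: ``(age_days, exact_age_years)``.

    In snap mode the exact ages are the integer age classes themselves
    (stored as the nearest whole day); in continuous mode exact ages are
    uniform over the feasible window at ``min_interval_days`` spacing.
    """
    lo, hi = config.age_range
    if config.age_placement == "snap":
        cmin, cmax = _round_half_up(lo), _round_half_up(hi)
        gap = max(1, math.ceil(config.min_interval_days / DAYS_PER_YEAR))
        width = cmax - cmin + 1 - (n_scans - 1) * (gap - 1)
        if width < n_scans:
            raise ValueError(
                f"cannot place {n_scans} scans with class gap {gap} in "
                f"classes [{cmin}, {cmax}]"
            )
        picks = np.sort(rng.choice(width, size=n_scans, replace=False))
        classes = cmin + picks + np.arange(n_scans) * (gap - 1)
        age_days = np.array(
            [_round_half_up(c * DAYS_PER_YEAR) for c in classes], dtype=int
        )
        return age_days, classes.astype(float)
    # continuous: uniform over the feasible simplex, in whole days
    lo_d = _round_half_up(lo * DAYS_PER_YEAR)
    hi_d = _round_half_up(hi * DAYS_PER_YEAR)
    slack = hi_d - lo_d - (n_scans - 1) * config.min_interval_days
    if slack < 0:
        raise ValueError(
            f"cannot place {n_scans} scans {config.min_interval_days} days "
            f"apart within ages [{lo}, {hi}] years"
        )
    u = np.sort(rng.integers(0, slack + 1, size=n_scans))
    age_days = lo_d + u + np.arange(n_scans) * config.min_interval_days
    return age_days, age_days / DAYS_PER_YEAR


def simulate_cohort(
    config: CohortConfig, seed: Optional[int] = None
) -> List[ScanRecord]:
    """Simulate a full scan panel.

    Deterministic given ``(config, seed)``; the patient roster (ids, sexes,
    scans per patient) depends only on the config, never on the seed.

    Raises
    ------
    ValueError
        If the config is invalid or the required scans cannot be placed
        within ``age_range`` at ``min_interval_days``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ln_base = math.log(config.base_mean_volume)
    half_asym = config.asymmetry_log_ratio / 2.0
    records: List[ScanRecord] = []
    for pid, sex, m in _patient_roster(config):
        age_days, t_years = _draw_scan_ages(config, m, rng)
        mu = np.atleast_1d(config.mean_log_curve(t_years))
        u_i = rng.normal(0.0, config.sd_individual) if config.sd_individual else 0.0
        walk = np.zeros(m)
        for s in range(1, m):
            dt = t_years[s] - t_years[s - 1]
            step_sd = config.sd_walk_per_year * math.sqrt(dt)
            walk[s] = walk[s - 1] + (rng.normal(0.0, step_sd) if step_sd else 0.0)
        for s in range(m):
            e_left = rng.normal(0.0, config.sd_measurement) if config.sd_measurement else 0.0
            e_right = rng.normal(0.0, config.sd_measurement) if config.sd_measurement else 0.0
            core = ln_base + mu[s] + u_i + walk[s]
            records.append(
                ScanRecord(
                    patient_id=pid,
                    sex=sex,
                    age_days=int(age_days[s]),
                    left_volume=math.exp(core - half_asym + e_left),
                    right_volume=math.exp(core + half_asym + e_right),
                )
            )
    return records


def simulate_reliability_measurements(
    true_volumes: Sequence[float],
    sd_operator: float,
    n_operators: int = 2,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Repeated measurements of known volumes under lognormal operator noise.

    Each operator x replicate cell of each orbit is
    ``true_volume * exp(Normal(0, sd_operator^2))``.  Returns a long-format
    frame with columns ``orbit_id, operator_id, replicate_id, volume_mm3``,
    suitable for the reliability statistics (intra-operator designs use one
    operator with several replicates; inter-operator designs several
    operators).
    """
    vols = np.asarray(true_volumes, dtype=float)
    if vols.ndim != 1 or vols.size == 0:
        raise ValueError("true_volumes must be a non-empty 1-D sequence")
    if np.any(vols <= 0):
        raise ValueError("true volumes must be strictly positive")
    if sd_operator < 0:
        raise ValueError("sd_operator must be >= 0")
    if n_operators < 1 or n_replicates < 1:
        raise ValueError("n_operators and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for o in range(n_operators):
        for r in range(n_replicates):
            noise = (
                rng.normal(0.0, sd_operator, size=vols.size)
                if sd_operator
                else np.zeros(vols.size)
            )
            measured = vols * np.exp(noise)
            for i, v in enumerate(measured):
                rows.append((f"orbit{i + 1:03d}", f"op{o + 1}", r + 1, v))
    return pd.DataFrame(
        rows, columns=["orbit_id", "operator_id", "replicate_id", "volume_mm3"]
    )


# ---------------------------------------------------------------------------
# CSV round-trip

_SCAN_COLUMNS = ["patient_id", "sex", "age_days", "left_volume_mm3", "right_volume_mm3"]


def records_to_frame(records: Iterable[ScanRecord]) -> pd.DataFrame:
    rows = [
        (r.patient_id, r.sex, r.age_days, r.left_volume, r.right_volume)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> List[ScanRecord]:
    missing = set(_SCAN_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"scan table missing columns: {sorted(missing)}")
    return [
        ScanRecord(
            patient_id=str(row.patient_id),
            sex=str(row.sex),
            age_days=int(row.age_days),
            left_volume=float(row.left_volume_mm3),
            right_volume=float(row.right_volume_mm3),
        )
        for row in frame.itertuples(index=False)
    ]


def write_scan_csv(records: Iterable[ScanRecord] | pd.DataFrame, path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, index=False)


def read_scan_csv(path) -> List[ScanRecord]:
    return frame_to_records(pd.read_csv(path))
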