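"""From raw scans to the estimation panel.

Raw scan records carry exact ages in days and one volume per orbital side.
The repeat-scan index works on a coarser object: per scan, the bilateral
mean volume assigned to an integer *age class*; per patient, the log-volume
growth between *consecutive* scans.  This module performs that reduction:

- age-class assignment: ``round(age_days / 365.25)`` to the nearest integer,
  half-up at ties, with scans rounding to 19 reclassified into class 18
  (the top class is thin);
- bilateral averaging of left and right volumes;
- consecutive-pair construction with log growth
  ``ln(volume_k) - ln(volume_j)``, ``k > j``.

A patient with m scans yields m - 1 pairs (adjacent scans only, not all
combinations).  Pairs whose two scans round to the same age class carry no
growth information and are dropped with a warning.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_YEAR, ScanRecord

__all__ = [
    "assign_age_class",
    "average_bilateral",
    "compute_growth",
    "build_panel",
    "build_growth_pairs",
    "write_pairs_csv",
    "read_pairs_csv",
]

#: Scans rounding to this class are merged into the class below.
TOP_AGE_CLASS = 18

PANEL_COLUMNS = ["patient_id", "sex", "age_days", "age_class", "mean_volume"]
PAIR_COLUMNS = ["patient_id", "j", "k", "interval", "growth"]


def assign_age_class(age_days: int) -> int:
    """Integer age class of a scan taken at ``age_days`` days of age.

    The exact age in years (days / 365.25) is rounded to the nearest
    integer, half-up at .5 ties; class 19 is reclassified to 18.

    >>> assign_age_class(3865)   # 10 years 7 months
    11
    >>> assign_age_class(7000)   # 19.2 years
    18
    """
    if age_days <= 0:
        raise ValueError("age_days must be positive")
    cls = int(math.floor(age_days / DAYS_PER_YEAR + 0.5))
    if cls == TOP_AGE_CLASS + 1:
        return TOP_AGE_CLASS
    if cls > TOP_AGE_CLASS + 1:
        raise ValueError(f"age class {cls} beyond supported range (<= 19)")
    return cls


def average_bilateral(left: float, right: float) -> float:
    """Arithmetic mean of the left and right orbital volumes (mm^3)."""
    if left <= 0 or right <= 0:
        raise ValueError("volumes must be strictly positive")
    return (left + right) / 2.0


def compute_growth(vol_k: float, vol_j: float) -> float:
    """Log growth ln(vol_k) - ln(vol_j) between two volumes (k later)."""
    if vol_k <= 0 or vol_j <= 0:
        raise ValueError("volumes must be strictly positive")
    return math.log(vol_k) - math.log(vol_j)


def build_panel(records: Iterable[ScanRecord] | pd.DataFrame) -> pd.DataFrame:
    """Panel observations: one row per scan with age class and mean volume.

    Returns a frame with columns ``patient_id, sex, age_days, age_class,
    mean_volume``, sorted by patient then age.  Duplicate
    ``(patient_id, age_days)`` entries raise.
    """
    if isinstance(records, pd.DataFrame):
        from .cohort import frame_to_records

        records = frame_to_records(records)
    rows = []
    for r in records:
        rows.append(
            (
                r.patient_id,
                r.sex,
                r.age_days,
                assign_age_class(r.age_days),
                average_bilateral(r.left_volume, r.right_volume),
            )
        )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    if panel.duplicated(subset=["patient_id", "age_days"]).any():
        dup = panel[panel.duplicated(subset=["patient_id", "age_days"], keep=False)]
        raise ValueError(
            "duplicate (patient_id, age_days) scans: "
            f"{sorted(set(dup.patient_id))}"
        )
    return panel.sort_values(["patient_id", "age_days"], kind="mergesort").reset_index(
        drop=True
    )


def build_growth_pairs(panel: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-scan growth pairs from a panel.

    One pair per adjacent scan pair within each patient.  Pairs whose scans
    fall in the same age class are dropped with a warning (they carry no
    growth information across classes).  Output columns:
    ``patient_id, j, k, interval, growth`` with ``interval = k - j`` years.
    """
    panel = panel.sort_values(["patient_id", "age_days"], kind="mergesort")
    if panel.duplicated(subset=["patient_id", "age_days"]).any():
        raise ValueError("duplicate (patient_id, age_days) scans")
    rows = []
    n_dropped = 0
    for pid, grp in panel.groupby("patient_id", sort=True):
        cls = grp["age_class"].to_numpy()
        vol = grp["mean_volume"].to_numpy()
        for a in range(len(grp) - 1):
            j, k = int(cls[a]), int(cls[a + 1])
            if k == j:
                n_dropped += 1
                continue
            rows.append((pid, j, k, k - j, compute_growth(vol[a + 1], vol[a])))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} consecutive pair(s) within a single age class",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def write_pairs_csv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, index=False)


def read_pairs_csv(path) -> pd.DataFrame:
    pairs = pd.read_csv(path)
    missing = set(PAIR_COLUMNS) - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    return pairs
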