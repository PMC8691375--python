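"""Annualized AAA growth, growth categories and feature-growth correlation.

Growth between a baseline and a follow-up scan is annualized as
``(APD_followup - APD_baseline) / (days_between / 365)`` (mm/yr) and
categorized as slow (< 2.5 mm/yr), some (2.5-5.0 mm/yr, boundaries
inclusive) or fast (> 5.0 mm/yr).  Cohort assembly enforces the serial-scan
inclusion rule of a minimum 8-month (244-day) interval between scans.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry_features import GeometricFeatures

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.0
#: Minimum days between serial scans ("greater than 8 months", 8 x 30.5).
MIN_INTERVAL_DAYS = 244

SLOW_THRESHOLD = 2.5  # mm/yr
FAST_THRESHOLD = 5.0  # mm/yr

CATEGORIES = ("slow", "some", "fast")


@dataclass
class GrowthRecord:
    """One patient's serial-scan observation."""

    patient_id: str
    baseline: GeometricFeatures
    apd_followup: float
    days_between: int
    annual_growth: float
    category: str

    def __post_init__(self) -> None:
        if self.days_between <= 0:
            raise ValueError("days_between must be positive")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class CandidatePair:
    """An unfiltered baseline/follow-up scan pair."""

    patient_id: str
    baseline: GeometricFeatures
    apd_followup: float
    day_baseline: int
    day_followup: int

    @property
    def days_between(self) -> int:
        return self.day_followup - self.day_baseline


def annual_growth(apd_baseline: float, apd_followup: float, days_between: float) -> float:
    """Annualized diameter growth in mm/yr; may be negative (shrinkage)."""
    if days_between <= 0:
        raise ValueError(f"days_between must be positive, got {days_between}")
    return (apd_followup - apd_baseline) / (days_between / DAYS_PER_YEAR)


def categorize_growth(rate: float) -> str:
    """Map a growth rate to slow / some / fast.

    The printed ranges "<2.5", "2.5-5.0", ">5.0" make the middle interval
    closed: exactly 2.5 and exactly 5.0 mm/yr are both "some".
    """
    if not math.isfinite(rate):
        raise ValueError(f"growth rate must be finite, got {rate}")
    if rate < SLOW_THRESHOLD:
        return "slow"
    if rate <= FAST_THRESHOLD:
        return "some"
    return "fast"


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)`` with the two-sided p-value from the t
    approximation.  Constant input is signaled with a ValueError (the rank
    correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def make_record(pair: CandidatePair) -> GrowthRecord:
    """Compute growth and category for one pair (no interval filtering)."""
    rate = annual_growth(pair.baseline.apd, pair.apd_followup, pair.days_between)
    return GrowthRecord(
        patient_id=pair.patient_id,
        baseline=pair.baseline,
        apd_followup=pair.apd_followup,
        days_between=pair.days_between,
        annual_growth=rate,
        category=categorize_growth(rate),
    )


def filter_cohort(pairs: Sequence[CandidatePair],
                  min_days: int = MIN_INTERVAL_DAYS) -> list[GrowthRecord]:
    """Apply the serial-scan inclusion rule and build growth records.

    Pairs with fewer than ``min_days`` between scans are dropped (the
    cohort rule: a historic scan more than 8 months before the
    preoperative scan); the number excluded is logged.
    """
    kept = [p for p in pairs if p.days_between >= min_days]
    dropped = len(pairs) - len(kept)
    if dropped:
        log.info("cohort filter: dropped %d of %d pairs with < %d-day interval",
                 dropped, len(pairs), min_days)
    return [make_record(p) for p in kept]


# ---------------------------------------------------------------------------
# Tabular round-trip (schema in volume_io.FEATURE_COLUMNS)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Growth records as a DataFrame in the cohort CSV schema."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "apd_baseline_mm": [r.baseline.apd for r in records],
            "ui_baseline": [r.baseline.ui for r in records],
            "min_rc_baseline_mm": [r.baseline.min_rc for r in records],
            "days_between": [r.days_between for r in records],
            "annual_growth_mm_yr": [r.annual_growth for r in records],
            "category": [r.category for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[GrowthRecord]:
    """Rebuild growth records from the cohort CSV schema.

    ``apd_followup`` is reconstructed from the growth identity
    ``apd_followup = apd_baseline + growth * days / 365``, which inverts
    exactly the construction used when records are assembled.
    """
    records = []
    for row in frame.itertuples(index=False):
        baseline = GeometricFeatures(
            apd=float(row.apd_baseline_mm),
            ui=float(row.ui_baseline),
            min_rc=float(row.min_rc_baseline_mm),
        )
        days = int(row.days_between)
        growth = float(row.annual_growth_mm_yr)
        records.append(
            GrowthRecord(
                patient_id=str(row.patient_id),
                baseline=baseline,
                apd_followup=baseline.apd + growth * (days / DAYS_PER_YEAR),
                days_between=days,
                annual_growth=growth,
                category=str(row.category),
            )
        )
    return records
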