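"""Coral-spawning observation processing.

Observation tables (site, lat, lon, date, n_events) are filtered to the
study area (68.33E-180E, 24.67S-24.67N, boundary-inclusive), aggregated
into monthly histograms — overall and separately per ENSO phase of the
April-March year containing each event — and classified: months with a
count above zero but below 10% of that histogram's maximum are "minor
spawning", months at or above the threshold "major spawning".  A coverage
report states which months could be excluded from a connectivity
computation for a given pelagic larval duration (PLD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "STUDY_BOUNDS",
    "SpawningCalendar",
    "filter_region",
    "monthly_histogram",
    "classify_months",
    "pld_month_coverage",
]

# lon_min, lon_max (degE), lat_min, lat_max
STUDY_BOUNDS = (68.33, 180.0, -24.67, 24.67)

NONE_ = "none"
MINOR = "minor"
MAJOR = "major"


@dataclass
class SpawningCalendar:
    phase: str  # "all" or an ENSO phase label
    counts: np.ndarray  # 12 monthly totals, January first
    classification: list = dc_field(default_factory=lambda: [NONE_] * 12)


def filter_region(records: pd.DataFrame, bounds=STUDY_BOUNDS) -> pd.DataFrame:
    """Keep records inside the study area (boundary-inclusive).

    Longitudes are normalized to [0, 360); malformed coordinates are
    rejected with a warning.
    """
    lon_min, lon_max, lat_min, lat_max = bounds
    df = records.copy()
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat.abs() > 90)
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} records with malformed coordinates")
    lon = np.mod(lon, 360.0)
    keep = (
        ~bad
        & (lat >= lat_min)
        & (lat <= lat_max)
        & (lon >= np.mod(lon_min, 360.0))
        & (lon <= np.mod(lon_max - 1e-12, 360.0) + 1e-12)
    )
    return df.loc[keep].reset_index(drop=True)


def _event_year(ts: pd.Timestamp) -> int:
    """April-March year label (the year of the April start)."""
    return ts.year if ts.month >= 4 else ts.year - 1


def monthly_histogram(records: pd.DataFrame, labels: dict, phase: str = "all") -> SpawningCalendar:
    """Sum events per calendar month over the years in the given phase."""
    counts = np.zeros(12, dtype=np.int64)
    skipped = 0
    for _, row in records.iterrows():
        ts = pd.Timestamp(row["date"])
        y = _event_year(ts)
        if y not in labels:
            skipped += 1
            continue
        if phase != "all" and labels[y] != phase:
            continue
        counts[ts.month - 1] += int(row.get("n_events", 1))
    if skipped:
        warnings.warn(f"excluded {skipped} records in unlabeled years")
    return SpawningCalendar(phase=phase, counts=counts)


def classify_months(calendar: SpawningCalendar) -> SpawningCalendar:
    """Label months none / minor / major by the 10%-of-maximum rule.

    A count equal to exactly 10% of the maximum counts as major ("below 10%"
    is minor).  An all-zero calendar is all none.
    """
    counts = np.asarray(calendar.counts)
    mx = counts.max()
    cls = []
    for c in counts:
        if c == 0:
            cls.append(NONE_)
        elif c < 0.1 * mx:
            cls.append(MINOR)
        else:
            cls.append(MAJOR)
    calendar.classification = cls
    return calendar


def pld_month_coverage(calendars: dict, pld_days: float) -> dict:
    """Months excludable from a connectivity computation for a given PLD.

    Larvae spawned in month e are taken to be pelagic through month
    e + ceil(pld_days / 30); month m is *covered* in a phase if some event
    month e satisfies m - ceil(pld_days/30) <= e <= m (mod 12).  The report
    lists, per phase and overall (months excludable in every phase), the
    1-based months with no larval presence.
    """
    w = max(0, math.ceil(pld_days / 30))
    excludable = {}
    for phase, cal in calendars.items():
        counts = np.asarray(cal.counts)
        covered = np.zeros(12, dtype=bool)
        for e in np.nonzero(counts > 0)[0]:
            for k in range(w + 1):
                covered[(e + k) % 12] = True
        excludable[phase] = [m + 1 for m in range(12) if not covered[m]]
    overall = sorted(set.intersection(*(set(v) for v in excludable.values()))) if excludable else []
    return {"pld_days": pld_days, "per_phase": excludable, "all_phases": overall}
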