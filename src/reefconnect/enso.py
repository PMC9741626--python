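"""ENSO phase classification and phase-aggregated anomaly composites.

Years run April 1 to March 31 and are labelled El Nino / La Nina / neutral
from an ONI-style index: the area-mean anomaly over the Nino3.4 box
(5S-5N, 170W-120W), smoothed with a centered 3-month running mean.  A warm
(cold) episode is at least five consecutive smoothed values above +0.5 degC
(below -0.5 degC).  A year takes the phase of the episode containing the
largest absolute smoothed index among that year's months; years touched by
no episode are neutral.

Fields are detrended per cell (OLS over the full record) before phase
aggregation; the seasonal cycle is removed within each phase aggregation
separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "EL_NINO",
    "LA_NINA",
    "NEUTRAL",
    "PHASES",
    "PhaseComposite",
    "detrend",
    "compute_oni",
    "classify_years",
    "aggregate_phase",
]

EL_NINO = "el_nino"
LA_NINA = "la_nina"
NEUTRAL = "neutral"
PHASES = (EL_NINO, LA_NINA, NEUTRAL)

NINO34_BOX = (-5.0, 5.0, 190.0, 240.0)  # lat_min, lat_max, lon_min (degE), lon_max


def detrend(field: xr.DataArray) -> xr.DataArray:
    """Remove the per-cell OLS linear trend (including the mean).

    All-NaN cells are left NaN.  Requires at least 2 time points.
    """
    T = field.sizes["time"]
    if T < 2:
        raise ValueError("detrend requires at least 2 time points per cell")
    vals = np.asarray(field.values, dtype=float)
    flat = vals.reshape(T, -1)
    t = np.arange(T, dtype=float)
    design = np.column_stack([np.ones(T), t])
    out = np.full_like(flat, np.nan)
    ok = ~np.isnan(flat).any(axis=0)
    if ok.any():
        coef, *_ = np.linalg.lstsq(design, flat[:, ok], rcond=None)
        out[:, ok] = flat[:, ok] - design @ coef
    return field.copy(data=out.reshape(vals.shape))


def compute_oni(field: xr.DataArray, box=NINO34_BOX) -> pd.Series:
    """Latitude-cosine-weighted box-mean anomaly, 3-month running mean.

    The first and last values of the centered running mean are undefined and
    reported as NaN.  Longitudes are handled on a 0-360 circle.
    """
    lat_min, lat_max, lon_min, lon_max = box
    lat = np.asarray(field["lat"].values, dtype=float)
    lon = np.mod(np.asarray(field["lon"].values, dtype=float), 360.0)
    lon_min, lon_max = np.mod(lon_min, 360.0), np.mod(lon_max, 360.0)
    lat_sel = (lat >= lat_min) & (lat <= lat_max)
    if lon_min <= lon_max:
        lon_sel = (lon >= lon_min) & (lon <= lon_max)
    else:  # box wraps the dateline
        lon_sel = (lon >= lon_min) | (lon <= lon_max)
    if not lat_sel.any() or not lon_sel.any():
        raise ValueError("index box does not intersect the grid")
    sub = field.isel(lat=np.where(lat_sel)[0], lon=np.where(lon_sel)[0])
    w = np.cos(np.deg2rad(sub["lat"].values))
    w2d = np.broadcast_to(w[:, None], (sub.sizes["lat"], sub.sizes["lon"]))
    vals = sub.values  # (time, lat, lon)
    mask = ~np.isnan(vals)
    wsum = np.where(mask, w2d, 0.0).sum(axis=(1, 2))
    raw = np.where(mask, vals * w2d, 0.0).sum(axis=(1, 2)) / np.where(wsum > 0, wsum, np.nan)
    smoothed = pd.Series(raw, index=pd.DatetimeIndex(field["time"].values)).rolling(
        3, center=True
    ).mean()
    smoothed.name = "oni"
    return smoothed


def _episodes(index: pd.Series, threshold: float, persistence: int):
    """Maximal runs of the smoothed index beyond +-threshold, >= persistence long."""
    vals = index.values
    episodes = []
    for sign, phase in ((1.0, EL_NINO), (-1.0, LA_NINA)):
        active = np.nan_to_num(sign * vals, nan=-np.inf) > threshold
        i = 0
        n = len(vals)
        while i < n:
            if active[i]:
                j = i
                while j < n and active[j]:
                    j += 1
                if j - i >= persistence:
                    episodes.append({"phase": phase, "start": i, "stop": j})
                i = j
            else:
                i += 1
    return episodes


def classify_years(
    index: pd.Series, threshold: float = 0.5, persistence: int = 5
) -> dict:
    """Label April-March years from a smoothed monthly index.

    Returns ``{year_of_april_start: phase}``.  Years only partially covered
    by the index are excluded with a warning.  Within a year, the episode
    containing the month of largest absolute index wins (warm preferred on an
    exact tie, for determinism).
    """
    idx = pd.DatetimeIndex(index.index)
    episodes = _episodes(index, threshold, persistence)
    in_episode = np.full(len(idx), -1, dtype=int)
    for k, ep in enumerate(episodes):
        in_episode[ep["start"] : ep["stop"]] = k

    years = sorted({ts.year if ts.month >= 4 else ts.year - 1 for ts in idx})
    labels = {}
    have = set(zip(idx.year, idx.month))
    for y in years:
        months = [(y + (1 if m < 4 else 0), m) for m in (4, 5, 6, 7, 8, 9, 10, 11, 12, 1, 2, 3)]
        if not all(m in have for m in months):
            warnings.warn(f"year {y} (Apr-Mar) only partially covered by the index; skipped")
            continue
        best = None
        for (yy, mm) in months:
            pos = int(np.where((idx.year == yy) & (idx.month == mm))[0][0])
            k = in_episode[pos]
            if k < 0 or np.isnan(index.values[pos]):
                continue
            mag = abs(float(index.values[pos]))
            phase = episodes[k]["phase"]
            key = (mag, 1 if phase == EL_NINO else 0)
            if best is None or key > best[0]:
                best = (key, phase)
        labels[y] = best[1] if best is not None else NEUTRAL
    return labels


@dataclass
class PhaseComposite:
    """Deseasonalized concatenation of all April-March years of one phase."""

    phase: str
    field: xr.DataArray  # dims (time, lat, lon); time is a 0..L-1 counter
    month_index: np.ndarray  # calendar month (1..12) of each slice
    years: tuple  # years (April starts) included, chronological


def aggregate_phase(field: xr.DataArray, labels: dict, phase: str) -> PhaseComposite:
    """Concatenate the months of all years with the given label, then remove
    the per-calendar-month mean computed within this aggregation."""
    years = sorted(y for y, p in labels.items() if p == phase)
    if not years:
        raise ValueError(f"no years labelled {phase}")
    if len(years) == 1:
        warnings.warn(
            f"phase {phase} contains a single year; deseasonalizing degenerates to zero"
        )
    idx = pd.DatetimeIndex(field["time"].values)
    pos = []
    for y in years:
        for m in (4, 5, 6, 7, 8, 9, 10, 11, 12, 1, 2, 3):
            yy = y + (1 if m < 4 else 0)
            where = np.where((idx.year == yy) & (idx.month == m))[0]
            if len(where) != 1:
                raise ValueError(f"field does not cover {yy}-{m:02d} exactly once")
            pos.append(int(where[0]))
    sub = field.isel(time=pos)
    months = idx[pos].month.values
    vals = np.asarray(sub.values, dtype=float)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            vals[sel] -= np.nanmean(vals[sel], axis=0)
    out = xr.DataArray(
        vals,
        dims=("time", "lat", "lon"),
        coords={
            "time": np.arange(len(pos)),
            "lat": field["lat"].values,
            "lon": field["lon"].values,
            "month": ("time", months),
        },
        name=field.name or "ssta",
    )
    return PhaseComposite(phase=phase, field=out, month_index=months, years=tuple(years))
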