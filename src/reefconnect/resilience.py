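"""Cumulative bleaching stress, connectivity-modulated vulnerability and the
recovery potential score.

Thermal-stress classes follow the bleaching-alert-area convention: "no
stress" and "watch" are 0, "warning" 2, "alert level 1" 3 and "alert
level 2" 4.  Degree-heating-week values map onto the same classes:
0 -> 0, (0, 4) -> 2, [4, 8) -> 3, [8, inf) -> 4.  Within each ENSO phase the
classes are summed over time per fine-grid pixel (t.s.baa / t.s.dhw) and
bilinearly interpolated onto the SST grid.

The connectivity-modulated bleaching vulnerability of a cell inside a
domain is CMBV = t.s.baa / sigma+, with sigma+ the domain strength restricted
to incoming and undirected positive links; where domains overlap the highest
CMBV wins, and sigma+ = 0 yields infinite CMBV (no external recruit supply).
Per phase, a candidate score of 1 marks cells with t.s.baa below the 25th
percentile of neutral-phase values (fine grid) or CMBV below the neutral
25th percentile; the recovery potential score (RPS) is the cell-wise sum of
the three phase candidates, so RPS = 3 flags cells favourable in every phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .deltamaps import UNDIRECTED, A_TO_B, B_TO_A, FunctionalNetwork

__all__ = [
    "dhw_to_class",
    "StressRaster",
    "cumulative_stress",
    "interpolate_to_grid",
    "sigma_plus",
    "cmbv",
    "compute_thresholds",
    "candidate_score",
    "rps",
]


def dhw_to_class(dhw):
    """Map degree-heating-weeks to bleaching-risk classes {0, 2, 3, 4}."""
    arr = np.asarray(dhw, dtype=float)
    if (arr < 0).any():
        raise ValueError("DHW must be >= 0")
    out = np.select([arr == 0, arr < 4, arr < 8], [0, 2, 3], default=4)
    return out if np.ndim(dhw) else int(out)


@dataclass
class StressRaster:
    """Cumulative stress on the fine grid, plus its SST-grid interpolation."""

    cumulative: xr.DataArray  # (lat, lon) on the fine grid
    interpolated: xr.DataArray | None = None  # (lat, lon) on the SST grid


def cumulative_stress(classes: xr.DataArray, month_positions=None) -> StressRaster:
    """Sum stress classes over (a phase's) months, per fine-grid pixel."""
    vals = np.asarray(classes.values)
    if not np.isin(np.unique(vals), (0, 2, 3, 4)).all():
        raise ValueError("class raster contains values outside {0, 2, 3, 4}")
    if month_positions is not None:
        month_positions = list(month_positions)
        if not month_positions:
            raise ValueError("phase has no months")
        sel = classes.isel(time=month_positions)
    else:
        sel = classes
    cum = sel.sum("time")
    cum.name = (classes.name or "stress") + "_cumulative"
    return StressRaster(cumulative=cum)


def interpolate_to_grid(cumulative: xr.DataArray, lat, lon) -> xr.DataArray:
    """Bilinear interpolation onto a target grid, clamped at the edges."""
    src_lat = np.asarray(cumulative["lat"].values, dtype=float)
    src_lon = np.asarray(cumulative["lon"].values, dtype=float)
    interp = RegularGridInterpolator(
        (src_lat, src_lon), np.asarray(cumulative.values, dtype=float), method="linear"
    )
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    qlat = np.clip(lat, src_lat.min(), src_lat.max())
    qlon = np.clip(lon, src_lon.min(), src_lon.max())
    pts = np.stack(np.meshgrid(qlat, qlon, indexing="ij"), axis=-1).reshape(-1, 2)
    out = interp(pts).reshape(len(lat), len(lon))
    return xr.DataArray(
        out, dims=("lat", "lon"), coords={"lat": lat, "lon": lon}, name=cumulative.name
    )


def sigma_plus(network: FunctionalNetwork, domain_id: str) -> float:
    """Domain strength over positive incoming and undirected links only."""
    total = 0.0
    for ln in network.links_of(domain_id):
        if ln.weight <= 0:
            continue
        incoming = (
            ln.direction == UNDIRECTED
            or (ln.direction == A_TO_B and ln.b == domain_id)
            or (ln.direction == B_TO_A and ln.a == domain_id)
        )
        if incoming:
            total += abs(ln.weight)
    return total


def cmbv(tsbaa: xr.DataArray, domains, sigma: dict) -> xr.DataArray:
    """Connectivity-modulated bleaching vulnerability on the SST grid.

    For each cell inside a domain, CMBV = t.s.baa / sigma+ of that domain;
    overlapping cells take the maximum across covering domains; sigma+ = 0
    gives +inf.  Cells in no domain are NaN (excluded from scoring).
    """
    vals = np.asarray(tsbaa.values, dtype=float)
    out = np.full(vals.shape, np.nan)
    for d in domains:
        s = sigma[d.id]
        for (r, c) in d.cells:
            # zero incoming connectivity -> no external recruit supply
            v = np.inf if s == 0 else vals[r, c] / s
            if np.isnan(out[r, c]) or v > out[r, c]:
                out[r, c] = v
    return tsbaa.copy(data=out).rename("cmbv")


def compute_thresholds(
    neutral_tsbaa_fine: xr.DataArray, neutral_cmbv: xr.DataArray, percentile: float = 25.0
) -> dict:
    """25th-percentile thresholds from the neutral phase.

    t.s.baa is thresholded at the highest (fine) resolution; CMBV on the SST
    grid.  The population is all cells with a defined value; percentiles use
    linear interpolation between order statistics.
    """
    baa_vals = np.asarray(neutral_tsbaa_fine.values, dtype=float).ravel()
    baa_vals = baa_vals[~np.isnan(baa_vals)]
    cmbv_vals = np.asarray(neutral_cmbv.values, dtype=float).ravel()
    cmbv_vals = cmbv_vals[~np.isnan(cmbv_vals)]
    if baa_vals.size == 0 or cmbv_vals.size == 0:
        raise ValueError("cannot compute thresholds from empty populations")
    return {
        "percentile": percentile,
        "tsbaa": float(np.percentile(baa_vals, percentile)),
        "cmbv": float(np.percentile(np.nan_to_num(cmbv_vals, posinf=np.finfo(float).max), percentile)),
    }


def candidate_score(tsbaa: xr.DataArray, cmbv_map: xr.DataArray, thresholds: dict) -> xr.DataArray:
    """1 where t.s.baa < p25(baa) or CMBV < p25(CMBV); 0 elsewhere.

    Cells with undefined CMBV (outside every domain) are scored by the
    t.s.baa criterion alone.
    """
    if "tsbaa" not in thresholds or "cmbv" not in thresholds:
        raise ValueError("thresholds must contain 'tsbaa' and 'cmbv'")
    if tsbaa.shape != cmbv_map.shape:
        raise ValueError("t.s.baa and CMBV grids do not match")
    b = np.asarray(tsbaa.values, dtype=float)
    v = np.asarray(cmbv_map.values, dtype=float)
    low_baa = b < thresholds["tsbaa"]
    with np.errstate(invalid="ignore"):
        low_cmbv = ~np.isnan(v) & (v < thresholds["cmbv"])
    out = (low_baa | low_cmbv).astype(np.int64)
    return tsbaa.copy(data=out).rename("candidate")


def rps(candidates) -> xr.DataArray:
    """Cell-wise sum of the three per-phase 0/1 candidate maps."""
    candidates = list(candidates)
    shapes = {c.shape for c in candidates}
    if len(shapes) != 1:
        raise ValueError("candidate maps are on different grids")
    total = np.zeros(candidates[0].shape, dtype=np.int64)
    for c in candidates:
        total = total + np.asarray(c.values, dtype=np.int64)
    return candidates[0].copy(data=total).rename("rps")
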