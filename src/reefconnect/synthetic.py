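"""Synthetic inputs with planted structure and exported ground truth.

Every downstream stage of the pipeline (phase compositing, domain
identification, network inference, resilience scoring, spawning histograms)
can be exercised offline with fields generated here.  The generator plants

* spatially contiguous blocks of grid cells that share a latent AR(1)
  anomaly signal plus independent cell-level noise ("domains"),
* lagged couplings between latent signals (directed ground-truth links),
* a Nino3.4-style monthly index with scripted warm/cold episodes,
* bleaching-alert-class and degree-heating-week rasters with block hotspots,
* a coral-spawning observation table with monthly seasonality.

Latent signals are stationary unit-variance AR(1) processes; a coupling
``source -> target`` at lag L with strength c mixes ``c * source(t - L)``
into the target latent and rescales the independent part so that the
population lagged correlation equals c.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "PlantedDomainSpec",
    "PlantedCouplingSpec",
    "SyntheticScenario",
    "GroundTruth",
    "HotspotSpec",
    "block_cells",
    "generate_ssta",
    "generate_enso_index",
    "generate_baa_raster",
    "generate_dhw_raster",
    "generate_spawning_table",
]

BAA_CLASSES = (0, 2, 3, 4)


class ScenarioError(ValueError):
    """Raised for inconsistent synthetic-scenario configuration."""


def block_cells(row0: int, row1: int, col0: int, col1: int) -> frozenset:
    """Rectangular block of (row, col) cells, end-exclusive."""
    return frozenset((r, c) for r in range(row0, row1) for c in range(col0, col1))


def _is_four_connected(cells) -> bool:
    cells = set(cells)
    if not cells:
        return False
    stack = [next(iter(cells))]
    seen = {stack[0]}
    while stack:
        r, c = stack.pop()
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in cells and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == cells


@dataclass(frozen=True)
class PlantedDomainSpec:
    """A contiguous cell block driven by one latent AR(1) signal."""

    id: str
    cells: frozenset
    ar1_coefficient: float = 0.2
    loading: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ScenarioError(f"{self.id}: ar1_coefficient must be in [0, 1)")
        if self.loading < 0:
            raise ScenarioError(f"{self.id}: loading must be >= 0")
        if self.noise_sd < 0:
            raise ScenarioError(f"{self.id}: noise_sd must be >= 0")
        if not _is_four_connected(self.cells):
            raise ScenarioError(f"{self.id}: cells are not a single 4-connected component")


@dataclass(frozen=True)
class PlantedCouplingSpec:
    """Ground-truth lagged link: target(t) receives coupling * source(t - lag)."""

    source: str
    target: str
    lag: int
    coupling: float

    def __post_init__(self):
        if not abs(self.coupling) < 1.0:
            raise ScenarioError("coupling magnitude must be < 1")


@dataclass
class SyntheticScenario:
    grid_shape: tuple
    n_months: int
    domains: list
    couplings: list = dc_field(default_factory=list)
    seed: int = 0
    lat_coords: np.ndarray | None = None
    lon_coords: np.ndarray | None = None
    background_ar1: float = 0.2
    background_sd: float = 1.0
    allow_overlap: bool = False

    def __post_init__(self):
        nlat, nlon = self.grid_shape
        if self.n_months < 24:
            raise ScenarioError("n_months must be >= 24")
        if self.lat_coords is None:
            # equatorial band by default: cos(lat) weights stay close to 1
            self.lat_coords = np.linspace(-10.0, 10.0, nlat)
        if self.lon_coords is None:
            self.lon_coords = np.linspace(120.0, 120.0 + nlon / 3.0, nlon)
        self.lat_coords = np.asarray(self.lat_coords, dtype=float)
        self.lon_coords = np.asarray(self.lon_coords, dtype=float)
        if len(self.lat_coords) != nlat or len(self.lon_coords) != nlon:
            raise ScenarioError("coordinate lengths do not match grid_shape")
        seen: dict = {}
        for dom in self.domains:
            for cell in dom.cells:
                r, c = cell
                if not (0 <= r < nlat and 0 <= c < nlon):
                    raise ScenarioError(f"{dom.id}: cell {cell} outside grid {self.grid_shape}")
                if cell in seen and not self.allow_overlap:
                    raise ScenarioError(
                        f"domains {seen[cell]} and {dom.id} overlap at {cell}; "
                        "set allow_overlap=True to permit this"
                    )
                seen[cell] = dom.id
        ids = {d.id for d in self.domains}
        if len(ids) != len(self.domains):
            raise ScenarioError("duplicate domain ids")
        for cpl in self.couplings:
            if cpl.source not in ids or cpl.target not in ids:
                raise ScenarioError(f"coupling references unknown domain {cpl.source}->{cpl.target}")
        total = {}
        for cpl in self.couplings:
            total[cpl.target] = total.get(cpl.target, 0.0) + cpl.coupling**2
        for tgt, s in total.items():
            if s >= 1.0:
                raise ScenarioError(f"couplings into {tgt} have summed squared strength >= 1")
        if self._coupling_order() is None:
            raise ScenarioError("couplings must form an acyclic graph")

    def _coupling_order(self):
        """Topological order of domain ids under the coupling DAG, or None."""
        ids = [d.id for d in self.domains]
        incoming = {i: [c for c in self.couplings if c.target == i] for i in ids}
        order, placed = [], set()
        while len(order) < len(ids):
            ready = [i for i in ids if i not in placed and all(c.source in placed for c in incoming[i])]
            if not ready:
                return None
            for i in ready:
                placed.add(i)
                order.append(i)
        return order


@dataclass
class GroundTruth:
    """Planted structure: label raster, domain cell sets, couplings, latents."""

    labels: np.ndarray  # (nlat, nlon) int, -1 = background
    domains: dict  # id -> sorted list of (row, col)
    couplings: list  # list of PlantedCouplingSpec
    latents: dict  # id -> latent signal, shape (n_months,)

    def to_json(self, path):
        payload = {
            "labels": self.labels.tolist(),
            "domains": {k: [list(c) for c in v] for k, v in self.domains.items()},
            "couplings": [
                {"source": c.source, "target": c.target, "lag": c.lag, "coupling": c.coupling}
                for c in self.couplings
            ],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def _ar1(rng: np.random.Generator, n: int, phi: float, n_series: int = 1) -> np.ndarray:
    """Stationary unit-variance AR(1) paths, shape (n_series, n)."""
    eps = rng.standard_normal((n_series, n))
    if phi == 0.0:
        return eps
    x = np.empty_like(eps)
    x[:, 0] = eps[:, 0]
    c = math.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + c * eps[:, t]
    return x


def _monthly_time(n_months: int, start: str = "1993-04") -> pd.DatetimeIndex:
    return pd.date_range(start=start + "-01", periods=n_months, freq="MS")


def generate_ssta(scenario: SyntheticScenario, start: str = "1993-04"):
    """Generate an anomaly field with planted domains and lagged couplings.

    Returns ``(field, truth)`` where ``field`` is an xarray DataArray with
    dims (time, lat, lon) and ``truth`` is a :class:`GroundTruth`.
    """
    rng = np.random.default_rng(scenario.seed)
    nlat, nlon = scenario.grid_shape
    T = scenario.n_months
    pad = max((abs(c.lag) for c in scenario.couplings), default=0)
    lead = 2 * pad + 4  # lead-in so lag-shifted segments stay inside the record
    N = T + 2 * lead

    order = scenario._coupling_order()
    by_id = {d.id: d for d in scenario.domains}
    base = {d.id: _ar1(rng, N, d.ar1_coefficient, 1)[0] for d in scenario.domains}
    incoming = {i: [c for c in scenario.couplings if c.target == i] for i in by_id}

    latent_full: dict = {}
    for did in order:
        cpls = incoming[did]
        if not cpls:
            latent_full[did] = base[did]
            continue
        mix = math.sqrt(max(0.0, 1.0 - sum(c.coupling**2 for c in cpls))) * base[did]
        for c in cpls:
            mix = mix + c.coupling * np.roll(latent_full[c.source], c.lag)
        latent_full[did] = mix

    sl = slice(lead, lead + T)
    latents = {k: v[sl].copy() for k, v in latent_full.items()}

    values = scenario.background_sd * _ar1(rng, T, scenario.background_ar1, nlat * nlon)
    values = values.reshape(nlat, nlon, T)
    labels = np.full((nlat, nlon), -1, dtype=int)
    for idx, dom in enumerate(scenario.domains):
        sig = dom.loading * latents[dom.id]
        for (r, c) in sorted(dom.cells):
            cell = sig.copy()
            if dom.noise_sd > 0:
                cell = cell + dom.noise_sd * rng.standard_normal(T)
            values[r, c, :] = cell if labels[r, c] < 0 else values[r, c, :] + cell
            labels[r, c] = idx

    field = xr.DataArray(
        np.moveaxis(values, -1, 0),
        dims=("time", "lat", "lon"),
        coords={
            "time": _monthly_time(T, start),
            "lat": scenario.lat_coords,
            "lon": scenario.lon_coords,
        },
        name="ssta",
    )
    truth = GroundTruth(
        labels=labels,
        domains={d.id: sorted(d.cells) for d in scenario.domains},
        couplings=list(scenario.couplings),
        latents=latents,
    )
    return field, truth


def generate_enso_index(
    episodes,
    n_months: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    start: str = "1993-04",
) -> pd.Series:
    """Scripted Nino3.4-style monthly index.

    ``episodes`` is a list of ``(start_month, end_month, amplitude)`` with
    0-based month offsets, end-exclusive; amplitude in deg C (negative for
    cold episodes).  With ``noise_sd = 0`` the series is exactly the scripted
    rectangles, so its 3-month running mean crosses the +-0.5 deg C phase
    thresholds only within scripted episodes.
    """
    occupied = np.zeros(n_months, dtype=bool)
    vals = np.zeros(n_months)
    for (s, e, amp) in episodes:
        if not (0 <= s < e <= n_months):
            raise ScenarioError(f"episode ({s}, {e}) outside record of {n_months} months")
        if occupied[s:e].any():
            raise ScenarioError("episodes overlap")
        occupied[s:e] = True
        vals[s:e] = amp
    if noise_sd > 0:
        vals = vals + noise_sd * np.random.default_rng(seed).standard_normal(n_months)
    return pd.Series(vals, index=_monthly_time(n_months, start), name="nino34")


@dataclass(frozen=True)
class HotspotSpec:
    """A rectangular hotspot of elevated bleaching class for a month span."""

    row0: int
    row1: int
    col0: int
    col1: int
    start_month: int
    n_months: int
    level: float  # BAA class in {2, 3, 4}, or DHW magnitude for the DHW variant


def generate_baa_raster(
    grid_shape_fine,
    n_months: int,
    hotspot_specs=(),
    seed: int | None = None,
    lat_coords=None,
    lon_coords=None,
    start: str = "1993-04",
) -> xr.DataArray:
    """Bleaching-alert-area class raster, values in {0, 2, 3, 4}.

    Configured hotspots receive their class for the configured span; the rest
    of the grid stays at 0 ("no stress"/"watch").  ``seed`` is accepted for
    interface uniformity; the raster itself is deterministic.
    """
    ny, nx = grid_shape_fine
    vals = np.zeros((n_months, ny, nx), dtype=np.int64)
    for h in hotspot_specs:
        if h.level not in BAA_CLASSES:
            raise ScenarioError(f"BAA class {h.level} not in {BAA_CLASSES}")
        if not (0 <= h.row0 < h.row1 <= ny and 0 <= h.col0 < h.col1 <= nx):
            raise ScenarioError("hotspot block outside fine grid")
        t0, t1 = h.start_month, min(n_months, h.start_month + h.n_months)
        vals[t0:t1, h.row0:h.row1, h.col0:h.col1] = int(h.level)
    if not np.isin(np.unique(vals), BAA_CLASSES).all():
        raise RuntimeError("internal error: class values outside {0,2,3,4}")
    return xr.DataArray(
        vals,
        dims=("time", "lat", "lon"),
        coords={
            "time": _monthly_time(n_months, start),
            "lat": np.linspace(-12.0, 12.0, ny) if lat_coords is None else np.asarray(lat_coords),
            "lon": np.linspace(120.0, 140.0, nx) if lon_coords is None else np.asarray(lon_coords),
        },
        name="baa_class",
    )


def generate_dhw_raster(
    grid_shape_fine,
    n_months: int,
    hotspot_specs=(),
    seed: int | None = None,
    lat_coords=None,
    lon_coords=None,
    start: str = "1993-04",
) -> xr.DataArray:
    """Degree-heating-week raster (deg C-weeks), hotspot blocks over zero background."""
    ny, nx = grid_shape_fine
    vals = np.zeros((n_months, ny, nx), dtype=float)
    for h in hotspot_specs:
        if h.level < 0:
            raise ScenarioError("DHW must be >= 0")
        if not (0 <= h.row0 < h.row1 <= ny and 0 <= h.col0 < h.col1 <= nx):
            raise ScenarioError("hotspot block outside fine grid")
        t0, t1 = h.start_month, min(n_months, h.start_month + h.n_months)
        vals[t0:t1, h.row0:h.row1, h.col0:h.col1] = float(h.level)
    out = generate_baa_raster(grid_shape_fine, n_months, (), seed, lat_coords, lon_coords, start)
    return out.copy(data=vals).rename("dhw")


def generate_spawning_table(
    sites,
    monthly_rates,
    n_years: int,
    seed: int = 0,
    start_year: int = 1993,
    return_counts: bool = False,
):
    """Poisson spawning-observation table with monthly seasonality.

    ``sites`` is a list of ``(site_id, lat, lon)``; ``monthly_rates`` either a
    length-12 sequence shared by all sites or a mapping site_id -> length-12
    rates (expected events per month per year).  One row is emitted per
    observed event.  Years run April to March starting in ``start_year``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counts = {}
    for (sid, lat, lon) in sites:
        rates = np.asarray(
            monthly_rates[sid] if isinstance(monthly_rates, dict) else monthly_rates, dtype=float
        )
        if rates.shape != (12,) or (rates < 0).any():
            raise ScenarioError("monthly_rates must be 12 non-negative values")
        for yr_off in range(n_years):
            for m_off in range(12):  # April (0) .. March (11)
                month = (3 + m_off) % 12 + 1
                year = start_year + yr_off + (1 if month < 4 else 0)
                n = rng.poisson(rates[month - 1])
                counts[(sid, year, month)] = n
                for _ in range(n):
                    day = int(rng.integers(1, 29))
                    rows.append(
                        {
                            "site": sid,
                            "lat": lat,
                            "lon": lon,
                            "date": pd.Timestamp(year=year, month=month, day=day),
                            "n_events": 1,
                        }
                    )
    table = pd.DataFrame(rows, columns=["site", "lat", "lon", "date", "n_events"])
    if not table.empty:
        table = table.sort_values(["site", "date"], kind="stable").reset_index(drop=True)
    return (table, counts) if return_counts else table
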