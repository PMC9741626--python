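"""Domain identification and lagged functional-network inference.

Given a deseasonalized anomaly composite on a lat/lon grid, this module

1. computes the *local homogeneity* of each grid cell — the average pairwise
   Pearson correlation among the time series in the cell's K-neighborhood
   (K = 8: the 3x3 square centred on the cell);
2. infers a homogeneity threshold ``delta`` as the (1 - alpha) quantile of a
   null distribution built from spatially distant random cell groups drawn
   from a spatially shuffled field (alpha = 1e-3 by default);
3. identifies *cores* (cells whose homogeneity is a local maximum above
   delta) and greedily expands and merges them into spatially contiguous,
   internally homogeneous *domains*;
4. forms each domain's signal X_A(t) = sum_i x_i(t) cos(phi_i), with phi_i
   the latitude of cell i, and connects domains whose signals correlate
   significantly at some lag in [-tau_max, tau_max], testing each lag with a
   t-test whose variance is estimated by Bartlett's formula to account for
   autocorrelation.

Lag-sign convention: the correlation at lag tau > 0 pairs a(t) with
b(t + tau), i.e. positive lags mean A leads B.  A link is undirected when the
interval spanned by its significant lags contains lag 0, directed A->B
(B->A) when all significant lags are strictly positive (negative).  The link
weight is the covariance of the two signals at the best lag tau*, and a
domain's strength is the sum of |weight| over its incident links.

Average pairwise correlations over a cell set S are computed through the
identity  sum_{i != j} z_i . z_j = ||sum_i z_i||^2 - |S|  for unit-norm,
zero-mean series z_i, which makes homogeneity evaluations O(T) per set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "Domain",
    "NetworkLink",
    "FunctionalNetwork",
    "LagTestResult",
    "local_homogeneity",
    "homogeneity_map",
    "infer_delta_threshold",
    "identify_domains",
    "domain_signal",
    "lagged_correlation_test",
    "infer_network",
    "regrid",
]

UNDIRECTED = "undirected"
A_TO_B = "a_to_b"
B_TO_A = "b_to_a"


@dataclass
class Domain:
    id: str
    cells: frozenset  # (row, col) grid indices, one 4-connected component
    signal: np.ndarray | None = None
    strength: float = 0.0


@dataclass(frozen=True)
class NetworkLink:
    a: str
    b: str
    weight: float  # covariance of the signals at tau*
    lag: int  # tau*, in months; positive = a leads b
    r_star: float  # correlation at tau*
    direction: str  # undirected | a_to_b | b_to_a
    significant_lags: tuple


@dataclass
class FunctionalNetwork:
    domains: list
    links: list
    parameters: dict = dc_field(default_factory=dict)

    def strengths(self) -> dict:
        s = {d.id: 0.0 for d in self.domains}
        for ln in self.links:
            s[ln.a] += abs(ln.weight)
            s[ln.b] += abs(ln.weight)
        return s

    def links_of(self, domain_id: str):
        return [ln for ln in self.links if domain_id in (ln.a, ln.b)]


# ---------------------------------------------------------------------------
# field preparation

def _radius_for_k(K: int) -> int:
    r = round(((K + 1) ** 0.5 - 1) / 2)
    if (2 * r + 1) ** 2 - 1 != K:
        raise ValueError(f"K={K} is not a full square neighborhood (use 8, 24, ...)")
    return r


def _normalized(field: xr.DataArray):
    """Unit-norm, zero-mean series per cell; zeros where masked.

    Returns (Z of shape (nlat, nlon, T), valid mask (nlat, nlon)).
    """
    vals = np.asarray(field.values, dtype=float)  # (T, nlat, nlon)
    T = vals.shape[0]
    x = np.moveaxis(vals, 0, -1)  # (nlat, nlon, T)
    valid = ~np.isnan(x).any(axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mu = np.nanmean(x, axis=-1, keepdims=True)
    xc = np.where(valid[..., None], x - mu, 0.0)
    nrm = np.sqrt((xc**2).sum(axis=-1))
    valid &= nrm > 0
    Z = np.where(valid[..., None], xc / np.where(nrm[..., None] > 0, nrm[..., None], 1.0), 0.0)
    return Z, valid


def _set_homogeneity(Z, cells) -> float:
    """Average pairwise correlation over a set of >= 2 valid cells."""
    rows = np.array(sorted(cells))
    m = len(rows)
    if m < 2:
        return np.nan
    S = Z[rows[:, 0], rows[:, 1], :].sum(axis=0)
    return ((S @ S) - m) / (m * (m - 1))


def homogeneity_map(field: xr.DataArray, K: int = 8) -> np.ndarray:
    """Local homogeneity of every cell (NaN where undefined)."""
    r = _radius_for_k(K)
    Z, valid = _normalized(field)
    nlat, nlon, T = Z.shape
    S = np.zeros((nlat, nlon, T))
    m = np.zeros((nlat, nlon))
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            r0, r1 = max(0, -dr), min(nlat, nlat - dr)
            c0, c1 = max(0, -dc), min(nlon, nlon - dc)
            S[r0:r1, c0:c1] += Z[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            m[r0:r1, c0:c1] += valid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    with np.errstate(invalid="ignore", divide="ignore"):
        h = ((S * S).sum(axis=-1) - m) / (m * (m - 1))
    h[~valid | (m < 3)] = np.nan  # need the cell plus >= 2 unmasked neighbors
    return h


def local_homogeneity(field: xr.DataArray, cell, K: int = 8) -> float:
    """Average pairwise correlation in the K-neighborhood of one cell."""
    return float(homogeneity_map(field, K)[cell[0], cell[1]])


# ---------------------------------------------------------------------------
# delta threshold

def infer_delta_threshold(
    field: xr.DataArray,
    alpha: float = 1e-3,
    K: int = 8,
    n_draws: int = 10_000,
    min_distance: int = 5,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of null neighborhood-size homogeneities.

    The null is built by spatially shuffling the valid cell series and
    repeatedly drawing K+1 cells whose pairwise Chebyshev distance exceeds a
    minimum separation (capped at min(grid)/10 so draws stay feasible on
    small grids).
    """
    rng = np.random.default_rng(seed)
    Z, valid = _normalized(field)
    nlat, nlon, T = Z.shape
    pos = np.argwhere(valid)
    n_valid = len(pos)
    if n_valid < 100:
        raise ValueError("need at least 100 unmasked cells to infer delta")
    dist = max(1, min(min_distance, min(nlat, nlon) // 10))
    g = K + 1

    # shuffle series over valid positions to destroy spatial correlation
    perm = rng.permutation(n_valid)
    flatZ = Z[pos[:, 0], pos[:, 1], :][perm]

    samples = np.empty(n_draws)
    got = 0
    guard = 0
    while got < n_draws:
        guard += 1
        if guard > 2000:
            raise RuntimeError("distance-constrained null draws are infeasible on this grid")
        n_try = max(1024, 2 * (n_draws - got))
        cand = rng.integers(0, n_valid, size=(n_try, g))
        ok = np.ones(n_try, dtype=bool)
        pr = pos[cand]  # (n_try, g, 2)
        for i in range(g):
            for j in range(i + 1, g):
                d = np.abs(pr[:, i] - pr[:, j]).max(axis=-1)
                ok &= d > dist
        idx = cand[ok]
        if idx.size == 0:
            continue
        take = idx[: n_draws - got]
        Ssum = flatZ[take].sum(axis=1)  # (k, T)
        h = ((Ssum * Ssum).sum(axis=-1) - g) / (g * (g - 1))
        samples[got : got + len(take)] = h
        got += len(take)
    return float(np.quantile(samples, 1.0 - alpha))


# ---------------------------------------------------------------------------
# domain identification

def _find_cores(h: np.ndarray, delta: float, K: int):
    """Cells whose homogeneity is a local max over the K-neighborhood and > delta.

    Ties are broken by (row, col) lexicographic order: the lexicographically
    smaller cell wins.
    """
    r = _radius_for_k(K)
    nlat, nlon = h.shape
    cores = []
    cand = np.argwhere(np.nan_to_num(h, nan=-np.inf) > delta)
    for (cr, cc) in cand:
        hc = h[cr, cc]
        is_max = True
        for dr in range(-r, r + 1):
            for dc in range(-r, r + 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = cr + dr, cc + dc
                if not (0 <= nr < nlat and 0 <= nc < nlon):
                    continue
                hn = h[nr, nc]
                if np.isnan(hn):
                    continue
                if hn > hc or (hn == hc and (nr, nc) < (cr, cc)):
                    is_max = False
                    break
            if not is_max:
                break
        if is_max:
            cores.append((int(cr), int(cc)))
    cores.sort(key=lambda rc: (-h[rc[0], rc[1]], rc))
    return cores


def _grow(Z, valid, core, delta, cell_threshold):
    """Greedy 4-connected expansion from a core cell.

    At each step the admissible 4-neighbor that maximizes the expanded
    domain's average pairwise correlation is added.  A candidate is
    admissible only if (a) the expanded homogeneity stays >= delta and
    (b) its mean correlation with the current member cells reaches
    ``cell_threshold`` — condition (b) keeps large domains from absorbing
    uncorrelated cells, to which the average pairwise homogeneity alone is
    insensitive (one stray cell changes it by O(1/|A|)).
    """
    nlat, nlon, T = Z.shape
    cells = {core}
    S = Z[core].copy()

    def neighbors(cell_set):
        out = set()
        for (r, c) in cell_set:
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nb[0] < nlat and 0 <= nb[1] < nlon and nb not in cell_set and valid[nb]:
                    out.add(nb)
        return out

    frontier = neighbors(cells)
    while frontier:
        cand = sorted(frontier)
        zc = np.stack([Z[c] for c in cand])  # (n, T)
        m = len(cells)
        mean_corr = (zc @ S) / m
        Snew = S[None, :] + zc
        h_new = ((Snew * Snew).sum(axis=-1) - (m + 1)) / ((m + 1) * m)
        admissible = (mean_corr >= cell_threshold) & (h_new >= delta)
        if not admissible.any():
            break
        k = int(np.argmax(np.where(admissible, h_new, -np.inf)))
        chosen = cand[k]
        cells.add(chosen)
        S = S + Z[chosen]
        frontier.discard(chosen)
        r, c = chosen
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nb[0] < nlat and 0 <= nb[1] < nlon and nb not in cells and valid[nb]:
                frontier.add(nb)
    return cells


def _adjacent_or_overlapping(a: set, b: set) -> bool:
    if a & b:
        return True
    for (r, c) in a:
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in b:
                return True
    return False


def _merge(Z, groups, delta):
    """Merge adjacent/overlapping groups best-first while the union stays
    homogeneous (>= delta) and the mean cross-correlation between the two
    groups is >= delta; iterate to a fixed point."""

    groups = [set(g) for g in groups]
    while True:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if not _adjacent_or_overlapping(groups[i], groups[j]):
                    continue
                union = groups[i] | groups[j]
                h_u = _set_homogeneity(Z, union)
                Si = Z[tuple(np.array(sorted(groups[i])).T)].sum(axis=0)
                Sj = Z[tuple(np.array(sorted(groups[j])).T)].sum(axis=0)
                cross = (Si @ Sj) / (len(groups[i]) * len(groups[j]))
                if h_u >= delta and cross >= delta:
                    key = (h_u, -i, -j)
                    if best is None or key > best[0]:
                        best = (key, i, j, union)
        if best is None:
            return groups
        _, i, j, union = best
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [union]


def identify_domains(
    field: xr.DataArray, delta: float, K: int = 8, min_size: int = 2, alpha: float = 1e-3
) -> list:
    """Expand and merge homogeneity cores into domains.

    Every returned domain is a single 4-connected component whose average
    pairwise cell correlation is >= delta.  Cell admission during expansion
    additionally requires the candidate's mean correlation with the domain
    to be significant at level ``alpha`` Bonferroni-corrected over the grid
    (a single correlation has a much wider null than the group-averaged
    homogeneity that delta calibrates, and every grid cell is a potential
    candidate).  Domains smaller than ``min_size`` cells are dropped.
    Distinct domains may overlap.
    """
    Z, valid = _normalized(field)
    T = Z.shape[-1]
    n_valid = int(valid.sum())
    cell_threshold = max(
        delta, float(stats.norm.ppf(1.0 - alpha / max(1, n_valid) / 2.0)) / np.sqrt(T)
    )
    h = homogeneity_map(field, K)
    cores = _find_cores(h, delta, K)
    if not cores:
        warnings.warn("no cores found; returning no domains")
        return []
    grown = []
    seen = set()
    for core in cores:
        cells = _grow(Z, valid, core, delta, cell_threshold)
        key = frozenset(cells)
        if len(cells) >= 2 and key not in seen:
            seen.add(key)
            grown.append(cells)
    merged = _merge(Z, grown, delta)
    merged = [g for g in merged if len(g) >= min_size]
    merged.sort(key=lambda g: min(g))
    domains = []
    for k, cells in enumerate(merged):
        dom = Domain(id=f"D{k:02d}", cells=frozenset(cells))
        dom.signal = domain_signal(dom, field)
        domains.append(dom)
    return domains


# ---------------------------------------------------------------------------
# signals and network inference

def domain_signal(domain: Domain, field: xr.DataArray) -> np.ndarray:
    """X_A(t) = sum_{i in A} x_i(t) cos(phi_i), phi_i the latitude of cell i."""
    if not domain.cells:
        raise ValueError("empty domain")
    lat = np.asarray(field["lat"].values, dtype=float)
    vals = np.asarray(field.values, dtype=float)  # (T, nlat, nlon)
    rows = np.array(sorted(domain.cells))
    series = vals[:, rows[:, 0], rows[:, 1]]
    if np.isnan(series).any():
        raise ValueError("domain contains masked cells")
    w = np.cos(np.deg2rad(lat[rows[:, 0]]))
    return series @ w


@dataclass
class LagTestResult:
    lags: np.ndarray  # -tau_max .. tau_max
    r: np.ndarray  # Pearson r at each lag (on the re-centered overlap)
    tstat: np.ndarray
    significant: np.ndarray  # boolean
    var_r: np.ndarray

    @property
    def significant_lags(self):
        return tuple(int(l) for l in self.lags[self.significant])


def _bartlett_var(a: np.ndarray, b: np.ndarray, T_eff: int) -> float:
    """Bartlett estimate of var(r) under the no-cross-correlation null.

    var(r) ~ (1/T')(1 + 2 sum_k rho_a(k) rho_b(k)), with the sum truncated at
    min(T/3, first lag where both sample autocorrelations fall inside
    +-2/sqrt(T)).
    """
    T = len(a)
    max_lag = max(1, T // 3)
    ra = _sm_acf(a, nlags=max_lag, fft=True)[1:]
    rb = _sm_acf(b, nlags=max_lag, fft=True)[1:]
    bound = 2.0 / np.sqrt(T)
    inside = (np.abs(ra) < bound) & (np.abs(rb) < bound)
    first = int(np.argmax(inside)) + 1 if inside.any() else max_lag
    L = min(max_lag, first)
    s = float((ra[:L] * rb[:L]).sum())
    return max(1.0 + 2.0 * s, 0.05) / T_eff


def lagged_correlation_test(
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    tau_max: int,
    sig: float = 0.03,
) -> LagTestResult:
    """Test the lagged correlation of two signals at every lag in
    [-tau_max, tau_max].

    At lag tau the overlapping T - |tau| samples (a(t), b(t + tau)) are
    re-centered and their Pearson correlation computed; the correlation's
    variance is estimated by Bartlett's formula from the two signals'
    autocorrelations, and the lag is significant when |r| / sqrt(var) exceeds
    the two-sided t critical value at level ``sig``.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signals must be equal-length 1-D arrays")
    T = len(a)
    if T < 24:
        raise ValueError("signals must have at least 24 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance signal")
    lags = np.arange(-tau_max, tau_max + 1)
    r = np.empty(len(lags))
    var_r = np.empty(len(lags))
    tstat = np.empty(len(lags))
    signif = np.zeros(len(lags), dtype=bool)
    for k, tau in enumerate(lags):
        if tau >= 0:
            aw, bw = a[: T - tau], b[tau:]
        else:
            aw, bw = a[-tau:], b[: T + tau]
        T_eff = len(aw)
        aw = aw - aw.mean()
        bw = bw - bw.mean()
        denom = np.sqrt((aw @ aw) * (bw @ bw))
        if denom == 0:
            raise ValueError("zero-variance signal on the lag overlap")
        r[k] = float(aw @ bw / denom)
        var_r[k] = _bartlett_var(a, b, T_eff)
        tstat[k] = r[k] / np.sqrt(var_r[k])
        crit = stats.t.ppf(1.0 - sig / 2.0, df=T_eff - 2)
        signif[k] = abs(tstat[k]) > crit
    return LagTestResult(lags=lags, r=r, tstat=tstat, significant=signif, var_r=var_r)


def _lag_cov(a: np.ndarray, b: np.ndarray, tau: int) -> float:
    T = len(a)
    if tau >= 0:
        aw, bw = a[: T - tau], b[tau:]
    else:
        aw, bw = a[-tau:], b[: T + tau]
    return float(np.cov(aw, bw, ddof=1)[0, 1])


def _best_lag(res: LagTestResult) -> int:
    """tau* = significant lag maximizing |r|; ties by smaller |tau|, then
    negative before positive."""
    sig_lags = res.lags[res.significant]
    sig_r = res.r[res.significant]
    order = sorted(
        range(len(sig_lags)),
        key=lambda i: (-abs(sig_r[i]), abs(sig_lags[i]), sig_lags[i]),
    )
    return int(sig_lags[order[0]])


def infer_network(
    domains,
    field: xr.DataArray | None = None,
    tau_max: int = 2,
    sig: float = 0.03,
    parameters: dict | None = None,
) -> FunctionalNetwork:
    """Connect every pair of domains with >= 1 significant lagged correlation.

    The link carries the covariance weight at the best lag tau*, the lag
    itself, and a direction: undirected when the significant-lag interval
    contains 0, A->B when all significant lags are positive (A leads B), and
    B->A when all are negative.  Domain strengths are recomputed as the sum
    of |weight| over incident links.
    """
    domains = list(domains)
    for d in domains:
        if d.signal is None:
            if field is None:
                raise ValueError(f"domain {d.id} has no signal and no field was given")
            d.signal = domain_signal(d, field)
    links = []
    for i in range(len(domains)):
        for j in range(i + 1, len(domains)):
            a, b = domains[i], domains[j]
            res = lagged_correlation_test(a.signal, b.signal, tau_max, sig)
            if not res.significant.any():
                continue
            tau_star = _best_lag(res)
            r_star = float(res.r[res.lags == tau_star][0])
            sig_lags = res.significant_lags
            if min(sig_lags) <= 0 <= max(sig_lags):
                direction = UNDIRECTED
            elif min(sig_lags) > 0:
                direction = A_TO_B
            else:
                direction = B_TO_A
            links.append(
                NetworkLink(
                    a=a.id,
                    b=b.id,
                    weight=_lag_cov(a.signal, b.signal, tau_star),
                    lag=tau_star,
                    r_star=r_star,
                    direction=direction,
                    significant_lags=sig_lags,
                )
            )
    net = FunctionalNetwork(
        domains=domains,
        links=links,
        parameters={"tau_max": tau_max, "sig": sig, **(parameters or {})},
    )
    strengths = net.strengths()
    for d in domains:
        d.strength = strengths[d.id]
    return net


# ---------------------------------------------------------------------------
# regridding

def regrid(field: xr.DataArray, factor: int) -> xr.DataArray:
    """Block-average regrid by an integer factor (mask-aware).

    A coarse cell is the mean of its unmasked fine cells; fully masked
    blocks stay masked.  The grid shape must be divisible by ``factor``.
    """
    T, nlat, nlon = field.shape
    if nlat % factor or nlon % factor:
        raise ValueError(f"grid shape {(nlat, nlon)} not divisible by factor {factor}")
    vals = np.asarray(field.values, dtype=float)
    blocks = vals.reshape(T, nlat // factor, factor, nlon // factor, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(blocks, axis=(2, 4))
    lat = np.asarray(field["lat"].values).reshape(-1, factor).mean(axis=1)
    lon = np.asarray(field["lon"].values).reshape(-1, factor).mean(axis=1)
    return xr.DataArray(
        out,
        dims=("time", "lat", "lon"),
        coords={"time": field["time"].values, "lat": lat, "lon": lon},
        name=field.name,
    )
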