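# Methods

This note documents the models and numerical choices behind `reefconnect`,
module by module, including the places where the design was genuinely open
and what the synthetic benchmarks do and do not demonstrate.

## ENSO phasing (`reefconnect.enso`)

Years run April 1 – March 31, so that a single ENSO event is not split
across two labels.  The index is the latitude-cosine-weighted mean anomaly
over a Niño3.4-style box, smoothed with a centered 3-month running mean
(undefined at the two record ends, the standard ONI convention).  A warm
(cold) episode is ≥ 5 consecutive smoothed values above +0.5 °C (below
−0.5 °C).

*Year attribution.* An episode can straddle the April boundary.  We assign
each year the phase of the episode containing the largest |smoothed index|
among that year's months; a year touched by no episode is neutral, and on
an exact magnitude tie the warm episode wins.  This peak-month rule is a
deterministic choice; other conventions (e.g. majority-of-months) differ
only for episodes nearly centered on the boundary.

Detrending is per-cell OLS (intercept + slope) over the full record,
*before* phase aggregation; the seasonal cycle is then removed within each
phase aggregation separately, so each composite has exactly zero mean per
calendar month by construction.  A phase containing a single year
deseasonalizes to identically zero and is flagged with a warning.

## Domain identification (`reefconnect.deltamaps`)

**Local homogeneity** of a cell is the average pairwise Pearson correlation
of the time series in its K-neighborhood (K = 8: the 3×3 square).  All
set-homogeneity evaluations use the identity
Σ_{i≠j} z_i·z_j = ‖Σ_i z_i‖² − m for unit-norm centered series, making them
O(T) per set.  Cells with fewer than two unmasked neighbors have undefined
homogeneity and cannot be cores.

**δ threshold.** δ is the (1 − α) quantile (α = 10⁻³) of a null built by
spatially shuffling the valid cell series and drawing 10,000 groups of K+1
cells with pairwise Chebyshev separation above min(5, min(grid)/10) cells
(the cap keeps the draw feasible on small grids; at the 60×60 benchmark
scale the separation is 5).  The shuffle destroys spatial structure, so the
null represents the homogeneity of unrelated cells at the observed marginal
distributions.

**Cores** are cells whose homogeneity exceeds δ and is a local maximum over
the K-neighborhood, ties broken lexicographically by (row, col).

**Expansion and merging.** Each core grows greedily: at every step the
admissible 4-neighbor maximizing the expanded domain's average pairwise
correlation is added.  Admissibility requires (a) expanded homogeneity ≥ δ
and (b) the candidate's mean correlation with the current members to be
significant.  Condition (b) exists because the average pairwise homogeneity
of an m-cell domain moves by only O(1/m) when one uncorrelated cell joins,
so a homogeneity-only stopping rule lets large domains absorb background
without bound.  The threshold for (b) is max(δ, z₁₋α′/₂/√T) with
α′ = α/n_cells — a Bonferroni correction over the grid, since every cell is
a potential candidate; δ itself calibrates group-averaged correlations,
whose null is much narrower than a single correlation's.  After expansion,
duplicate domains are dropped and adjacent or overlapping domains are
merged best-first (by union homogeneity) while the union stays ≥ δ *and*
the mean cross-correlation between the two cell sets is ≥ δ; the second
condition prevents two large, internally tight but mutually unrelated
domains from merging on the strength of their internal correlations alone.
Domains may overlap; domains smaller than 2 cells are discarded.

This growth/merge procedure is this package's deterministic realization of
"cores are expanded and merged"; the admission significance test and the
cross-correlation merge condition are the two places where we depart from a
pure average-homogeneity rule, for the reasons above.

**Domain signal and network.** X_A(t) = Σ_{i∈A} x_i(t)·cos φ_i with φ_i the
cell latitude (an area-weighted cumulative anomaly).  For each domain pair
and each lag τ ∈ [−τ_max, τ_max] (lag τ > 0 pairs a(t) with b(t+τ): A leads
B), the Pearson correlation is computed on the re-centered T − |τ| overlap.
Its null variance is estimated by Bartlett's formula,
var(r) ≈ (1/T′)(1 + 2 Σ_k ρ_a(k)ρ_b(k)), truncating the sum at
min(T/3, first lag where both sample autocorrelations fall inside ±2/√T);
the statistic r/√var(r) is compared with the two-sided t critical value at
level 0.03 (df = T′ − 2).  The measured type-I rate on AR(1) φ = 0.5 pairs
at T = 288 is ≈ 0.03, inside [0.015, 0.06].

A link's lag τ* maximizes |r| among significant lags (ties: smaller |τ|,
then negative before positive — whether r or |r| should be maximized is
ambiguous for negative links; we use |r| so anticorrelated pairs keep their
strongest lag).  The weight is the signal covariance at τ* (sample
covariance, ddof = 1).  A link is undirected when the interval spanned by
its significant lags contains 0; otherwise all significant lags share one
sign and the link is directed from the leading domain.  Reading "includes
lag 0" as an interval also settles the mixed-sign case ({−1, +2} →
undirected).  Strength = Σ|w| over incident links, recomputed after
inference (an exact invariant asserted in the tests).

## Network metrics (`reefconnect.metrics`)

The positive unweighted graph keeps links with r(τ*) ≥ 0.35; undirected
links become two arcs, directed links one.  Centralities solve
c = α_F aᵀ d c + β (d = diag(1/max(1, d_out)), β = 1/N, α_F = 0.85) by
fixed-point iteration to ∞-norm 10⁻¹² (max 10⁵ iterations); a direct linear
solve is the test oracle, and the two agree to well below 10⁻⁸ on random
graphs up to 50 nodes.  Note c is not normalized to a probability vector —
the constant-β formulation is used as stated.

The biodiversity score picks the reference phase with most domains, maps
each phase's centralities to grid cells (a cell covered by several domains
takes their mean — an unbiased, order-independent attribution; per-domain
overlap weighting would be an alternative), averages over the reference
domain's covered cells per phase, then averages across phases that cover
the domain at all.  A domain uncovered in every phase has no score.

**Supercommunities** use deterministic weighted label propagation anchored
on strength: nodes are visited in descending (strength, id) order and adopt
the community label with the largest total |weight| of connecting links
(ties keep the current label when possible, else the smallest label),
iterated to a fixed point; isolated nodes stay singletons.  The original
seed-based formulation (strength local maxima as seeds) is unstable under
strength ties — a weak inter-community link can let one community's node
disqualify the other's seed — whereas label propagation recovers planted
two-block partitions (intra-weight 1.0, inter-weight 0.1) exactly and is
invariant to order-preserving relabeling.

## Resilience (`reefconnect.resilience`)

Stress classes: no stress/watch → 0, warning → 2, alert level 1 → 3, alert
level 2 → 4; DHW maps 0 → 0, (0, 4) → 2, [4, 8) → 3, [8, ∞) → 4.  Cumulative
stress is the exact integer sum of classes over a phase's months on the
fine grid, bilinearly interpolated to the SSTa grid (edge queries clamp to
the source grid's extent to avoid extrapolation).  σ⁺ sums |w| over a
domain's positive-weight links that are undirected or directed toward it.
CMBV = t.s.baa/σ⁺ per covered cell, with the maximum across overlapping
domains, and σ⁺ = 0 ⇒ CMBV = +∞ (no external recruit supply; such cells can
only qualify through low stress).  Candidate thresholds are 25th
percentiles (linear interpolation between order statistics) computed in the
neutral phase: t.s.baa on the fine grid over all cells with defined values,
CMBV over all defined (domain-covered) cells — whether the population
should be restricted to reef cells is not determinable here, so all defined
ocean cells are used.  The candidate is 1 where t.s.baa < p25 *or*
CMBV < p25 ("and/or" read as inclusive or); cells outside every domain are
scored by the stress criterion alone.  RPS is the exact integer sum of the
three phase candidates.  The DHW route (classes → t.s.dhw → CMBV → RPS)
is byte-equivalent to the BAA route when fed equal class rasters, which the
tests assert.

## Spawning (`reefconnect.spawning`)

Region filtering is boundary-inclusive with longitudes normalized to
[0, 360).  Events are attributed to April–March years; per-phase monthly
histograms are classified with the 10%-of-maximum rule, with a count
exactly at 10% counted as major ("below" is minor).  PLD coverage treats
larvae spawned in month e as pelagic through month e + ceil(pld/30); a
month no event covers in any phase is excludable.  The coverage report is
informational — it justifies the lag window but does not feed back into the
network inference.

## Synthetic data (`reefconnect.synthetic`)

Latent domain signals are stationary unit-variance AR(1) processes — the
minimal red-spectrum model that exercises the Bartlett correction; real
SSTa have richer (multi-scale, seasonally modulated) spectra.  A coupling
source → target at lag L with strength c replaces the target latent by
√(1−Σc²)·own + Σ c·source(t−L), so the population lagged correlation equals
c exactly.  Cell series are loading × latent + independent Gaussian noise;
background cells are independent AR(1).  Ground truth (cell-label raster,
domain cell lists, coupling list, latents) is exported so recovery metrics
need no re-derivation.  Generation is bit-reproducible per seed.

What the generator does *not* emulate: mesoscale advection, propagating
anomalies (domain boundaries in real fields are gradual, not blocky),
spatially correlated background noise, or realistic ENSO teleconnection
patterns.  Passing the recovery benchmarks therefore demonstrates that the
algorithmic chain is correct and well-calibrated under its own statistical
assumptions — not that real-ocean ecoregions would be recovered with the
same fidelity.

### Benchmark conditions and problem sizes

The recovery benchmarks use five 10×10-cell domains (loading 0.9, cell
noise sd 0.5, within-domain correlation ≈ 0.76) on a 60×60 grid with
T = 288 months, 10 realizations; link recovery uses two 6×6-cell domains
with a lag-2 coupling of 0.6 over 50 realizations, with near-white latents
(φ = 0.05) so that coupling leakage into adjacent lags (0.6·φ) stays an
order of magnitude below the detection threshold and the lag-window sweep
(τ_max = 1 vs 2) is clean.  With three null lags tested at the 3% level,
the per-realization probability that the directed lag-2 link is recovered
cleanly is ≈ 0.91, and the false-link rate at τ_max = 1 is bounded by the
family-wise level 1 − 0.97³ ≈ 0.09; the tests assert at those levels with
Monte-Carlo slack.  The bundled pipeline scenario uses a 30×30 grid and 24
April–March years split 8/8/8 between phases — matching the phase
composition the analysis design assumes — which gives 96-month composites,
enough for the per-cell admission test at the corrected significance level.

## Degenerate inputs and numerical details

- Masked (NaN) cells are excluded from all statistics; all-NaN cells stay
  NaN through detrending; fully masked regrid blocks stay masked.
- Zero-variance signals are rejected by the correlation test.
- The Bartlett variance estimate is floored at 0.05/T′ to guard against
  pathological negative autocorrelation sums.
- Percentile and quantile computations use NumPy's linear interpolation.
- Fixed-point PageRank tolerance 10⁻¹² in the ∞-norm; residuals are stored
  on the result for post-hoc verification.
- All file writers are deterministic (sorted JSON keys, fixed column
  order, full-precision `repr` for floats in CSV), so a rerun with the same
  configuration and seed reproduces every artifact checksum.

## Known limitations

- The expansion/merge procedure is a documented stand-in for the original
  domain-growth algorithm, whose precise ordering is not specified here;
  results on strongly overlapping real-world domains may differ.
- The clustering behind supercommunities is likewise a deterministic
  stand-in; no claim of equivalence to any published community-detection
  method is made.
- The ONI implementation uses the record's own climatology; it will not
  numerically reproduce official ONI values (different baseline).
- Species-specific larval mortality and settlement competency are outside
  scope; the spawning module uses pelagic larval duration only.
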