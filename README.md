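# reefconnect

Ecoregionalization, functional connectivity and bleaching-recovery scoring
for coral reef systems, from monthly sea-surface-temperature anomaly (SSTa)
fields.

Large-scale larval exchange between distant reefs underpins coral
biodiversity and recovery after bleaching, but it is hard to observe
directly.  Because SSTa at tropical latitudes co-varies with surface
currents, the spatial and lagged correlation structure of an SSTa field
carries a usable signal of physical connectivity.  `reefconnect` turns that
signal into quantitative products for conservation-oriented analysis:

1. **ENSO phase compositing** — April–March years are classified as
   El Niño / La Niña / neutral from an ONI-style index (3-month running-mean
   anomaly over the Niño3.4 box; an episode needs |index| > 0.5 °C for ≥ 5
   consecutive months), and detrended, per-phase deseasonalized SSTa
   composites are formed.
2. **Domain identification and network inference** — spatially contiguous,
   internally homogeneous regions ("domains", read as ecoregions) are found
   from local homogeneity cores above a threshold δ (inferred from a null
   distribution at level α = 10⁻³), expanded and merged.  Each domain's
   signal is the latitude-weighted cumulative anomaly
   X_A(t) = Σ_{i∈A} x_i(t)·cos φ_i.  Domains A, B are linked when their
   signals correlate significantly at some lag τ ∈ [−τ_max, τ_max]
   (per-lag t-test at level 0.03 with Bartlett's autocorrelation
   correction); the link weight is the signal covariance at the best lag τ*,
   the direction follows the sign of the significant-lag range, and a
   domain's strength is Σ|w| over incident links.
3. **Biodiversity scores** — per phase, PageRank centralities of the
   positive unweighted network (links with r ≥ 0.35) are solved from
   c = α_F aᵀ·d·c + β with d = diag(1/max(1, d_out)), α_F = 0.85,
   β = 1/N; the biodiversity score of a domain averages the three phase
   centralities over its geographic footprint.  A deterministic
   strength-ordered clustering groups domains into supercommunities.
4. **Recovery potential** — bleaching-alert-area classes (no stress/watch
   → 0, warning → 2, alert 1 → 3, alert 2 → 4; degree-heating-weeks map to
   the same classes) are summed over each phase's months into cumulative
   stress t.s.baa, interpolated onto the SSTa grid, and combined with
   connectivity as CMBV = t.s.baa / σ⁺ (σ⁺ = strength over incoming and
   undirected positive links; overlapping domains keep the worst CMBV).
   Cells below the neutral-year 25th percentile of t.s.baa or CMBV score a
   candidate 1 per phase; the recovery potential score RPS (0–3) is the sum
   over the three phases.
5. **Spawning calendars** — coral-spawning observation tables are filtered
   to the study region (68.33°E–180°E, 24.67°S–24.67°N), aggregated into
   per-phase monthly histograms, classified major/minor (10%-of-maximum
   rule), and checked for months excludable at a given pelagic larval
   duration.

A synthetic-data module generates every input the pipeline needs — SSTa
fields with planted domains and lagged couplings plus exported ground truth,
scripted ENSO indices, structured stress rasters and seasonal spawning
tables — so the whole chain is testable offline.

## Worked example

```sh
reefconnect -v run-all --outdir run --seed 1
```

```
reefconnect: stage inputs complete (T=288 months, grid 30x30)
reefconnect: stage phasing: {'el_nino': 8, 'la_nina': 8, 'neutral': 8}
reefconnect: stage networks/el_nino: delta=0.0903, 3 domains, 1 links
reefconnect: stage networks/la_nina: delta=0.0862, 3 domains, 1 links
reefconnect: stage networks/neutral: delta=0.0841, 3 domains, 1 links
reefconnect: stage resilience: RPS histogram [635, 23, 2, 240]
run complete: 27 artifacts in run
```

The bundled scenario plants three 5×5-cell domains (A, B, C) in a 30×30
grid over 24 April–March years (8 per ENSO phase) with a directed A→B
coupling at lag 2 months.  The run recovers all three domains exactly in
every phase (`planted_recovery.json` reports Jaccard 1.0 against ground
truth) and the neutral-phase network contains the planted link:

```
     a    b  lag direction    r_star
0  D00  D01    2    a_to_b  0.485617
```

i.e. domain D00 (= planted A) leads D01 (= planted B) by 2 months — larvae
spawned in A could seed B one to two months later.  `centrality.csv` holds
the per-phase PageRank centralities and, for the reference phase (the one
with most domains), the averaged biodiversity score; e.g. D01, the planted
coupling's point of arrival, scores highest (1.15 vs 0.96 and 0.33).  The
RPS histogram above says 240 of 900 grid cells are favourable in all three
phases (RPS = 3): low cumulative stress or high incoming connectivity
regardless of ENSO state.  `spawning_report.json` classifies the synthetic
spawning peak (March–May, September–December) and reports that with a
30-day larval duration only February, July and August could be excluded
from a connectivity computation in every phase.

Each stage can also be run separately (`simulate`, `phase`, `domains`,
`network`, `centrality`, `spawning`); `run-all` writes `manifest.json` with
a SHA-256 checksum per artifact, and re-running with the same configuration
and seed reproduces it byte for byte.

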