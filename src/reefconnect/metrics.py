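"""Per-phase positive graphs, PageRank centralities, biodiversity scores and
supercommunity detection.

The biodiversity hypothesis: an ecoregion is biodiverse when it is a point
of arrival for many connections.  Arrival-ness is quantified with PageRank
centrality on the *positive unweighted* network — links whose best-lag
correlation is at least ``r_min`` (0.35 by default) — solved as

    c = alpha_F * a^T . d . c + beta,

where ``a`` is the adjacency matrix, ``d`` the diagonal matrix with entries
1 / max(1, d_i_out), ``alpha_F`` the damping factor (0.85) and ``beta`` the
constant vector 1 / N_nodes.  The averaged *biodiversity score* maps each
phase's centralities onto grid cells (mean over covering domains) and, for
each reference-phase domain, averages the three phase values over the
domain's footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .deltamaps import UNDIRECTED, A_TO_B, B_TO_A, FunctionalNetwork

__all__ = [
    "build_positive_graph",
    "pagerank",
    "CentralityResult",
    "reference_phase",
    "centrality_cell_map",
    "biodiversity_score",
    "detect_supercommunities",
]


def build_positive_graph(network: FunctionalNetwork, r_min: float = 0.35) -> nx.DiGraph:
    """Directed graph of the links with best-lag correlation >= r_min.

    Undirected links contribute arcs both ways; directed links one arc in
    the lead direction.  Weights are dropped (the graph is unweighted).
    """
    g = nx.DiGraph()
    g.add_nodes_from(d.id for d in network.domains)
    for ln in network.links:
        if ln.r_star < r_min:
            continue
        if ln.direction == UNDIRECTED:
            g.add_edge(ln.a, ln.b)
            g.add_edge(ln.b, ln.a)
        elif ln.direction == A_TO_B:
            g.add_edge(ln.a, ln.b)
        elif ln.direction == B_TO_A:
            g.add_edge(ln.b, ln.a)
    return g


@dataclass
class CentralityResult:
    phase: str
    centralities: dict  # node -> c
    alpha_f: float
    beta: float
    residual: float  # ||c - (alpha_F a^T d c + beta)||_inf


def pagerank(
    graph: nx.DiGraph,
    alpha_f: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    phase: str = "",
) -> CentralityResult:
    """Fixed-point solution of c = alpha_F a^T d c + beta, beta = 1/N.

    Dangling nodes are handled through the max(1, d_out) rule: their (empty)
    column simply contributes nothing.  Unique for alpha_F < 1.
    """
    if not 0.0 < alpha_f < 1.0:
        raise ValueError("alpha_f must be in (0, 1)")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)  # a[i, j] = 1 if i -> j
    dout = a.sum(axis=1)
    d = 1.0 / np.maximum(1.0, dout)
    m = a.T * d[None, :]  # (a^T d)[i, j] = a[j, i] / max(1, dout_j)
    beta = 1.0 / n
    c = np.full(n, beta)
    for _ in range(max_iter):
        c_new = alpha_f * (m @ c) + beta
        if np.max(np.abs(c_new - c)) < tol:
            c = c_new
            break
        c = c_new
    residual = float(np.max(np.abs(c - (alpha_f * (m @ c) + beta))))
    return CentralityResult(
        phase=phase,
        centralities={nd: float(v) for nd, v in zip(nodes, c)},
        alpha_f=alpha_f,
        beta=beta,
        residual=residual,
    )


def reference_phase(per_phase_domains: dict) -> str:
    """The phase with the most domains (ties to the lexicographically first)."""
    return sorted(per_phase_domains, key=lambda p: (-len(per_phase_domains[p]), p))[0]


def centrality_cell_map(domains, centralities: dict, grid_shape) -> np.ndarray:
    """Per-cell centrality: mean over covering domains, NaN where uncovered."""
    acc = np.zeros(grid_shape)
    cnt = np.zeros(grid_shape)
    for d in domains:
        c = centralities[d.id]
        for (r, col) in d.cells:
            acc[r, col] += c
            cnt[r, col] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    return out


def biodiversity_score(
    reference_domains,
    per_phase_centralities: dict,
    per_phase_domains: dict,
    grid_shape,
) -> dict:
    """Average of the three phase centralities over each reference domain.

    For each phase, centralities are first attributed to grid cells (mean of
    covering domains); the phase value of a reference domain is the mean over
    its covered cells.  The score averages the phase values over the phases
    that cover the domain at all; a domain uncovered in every phase gets NaN.
    """
    phase_maps = {
        p: centrality_cell_map(per_phase_domains[p], per_phase_centralities[p], grid_shape)
        for p in per_phase_centralities
    }
    scores = {}
    for dom in reference_domains:
        rows = np.array(sorted(dom.cells))
        vals = []
        for p, cmap in sorted(phase_maps.items()):
            cell_vals = cmap[rows[:, 0], rows[:, 1]]
            if np.isnan(cell_vals).all():
                continue
            vals.append(float(np.nanmean(cell_vals)))
        scores[dom.id] = float(np.mean(vals)) if vals else float("nan")
    return scores


def detect_supercommunities(network: FunctionalNetwork) -> dict:
    """Deterministic centrality-ordered partition of the functional network.

    Weighted label propagation, anchored on domain strength: every node
    starts in its own community; nodes are visited in descending
    (strength, id) order, and each adopts the community label carrying the
    largest total |weight| of connecting links (a tie keeps the current
    label if it is among the best, otherwise takes the lexicographically
    smallest), iterated to a fixed point.  Strong domains therefore settle
    community labels first and weakly attached nodes follow them.  Isolated
    nodes remain singleton communities.  Returns ``{node: community_label}``.
    """
    if not network.domains:
        raise ValueError("empty network")
    strength = network.strengths()
    w = {}
    nbrs = {d.id: set() for d in network.domains}
    for ln in network.links:
        w[(ln.a, ln.b)] = w.get((ln.a, ln.b), 0.0) + abs(ln.weight)
        w[(ln.b, ln.a)] = w.get((ln.b, ln.a), 0.0) + abs(ln.weight)
        nbrs[ln.a].add(ln.b)
        nbrs[ln.b].add(ln.a)

    nodes = sorted(nbrs, key=lambda nd: (-strength[nd], nd))
    member = {nd: nd for nd in nodes}
    for _ in range(2 * len(nodes) + 1):
        changed = False
        for nd in nodes:
            totals = {}
            for nb in nbrs[nd]:
                lbl = member[nb]
                totals[lbl] = totals.get(lbl, 0.0) + w[(nd, nb)]
            if not totals:
                continue
            top = max(totals.values())
            candidates = sorted(lbl for lbl, v in totals.items() if v == top)
            best = member[nd] if member[nd] in candidates else candidates[0]
            if member[nd] != best:
                member[nd] = best
                changed = True
        if not changed:
            break
    return member
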