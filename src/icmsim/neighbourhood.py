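"""Delaunay neighbourhoods, composition statistics and their comparison.

Two cells are neighbours iff they share an edge of the 3D Delaunay
triangulation of cell centres.  For each centre type j, the neighbourhood
composition row is computed from the pooled multiset of all neighbours of
all type-j cells (a cell adjacent to two type-j centres counts twice),
normalised to proportions.  Simulated and reference composition sets are
compared entrywise with the two-sided Wilcoxon–Mann–Whitney rank-sum test
(normal approximation, tie-corrected) under Bonferroni correction, and
summarised by the effect size psi — the mean relative deviation
|s - m| / m over the 16 (centre, neighbour) entries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.stats import mannwhitneyu

from .errors import DegenerateInputError
from .fate_model import as_proportions
from .types import N_TYPES, TYPE_NAMES, etype_codes

__all__ = [
    "AdjacencyGraph",
    "NeighbourhoodStats",
    "delaunay_adjacency",
    "neighbourhood_composition",
    "effect_size_psi",
    "compare_compositions",
    "same_type_enrichment",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, irreflexive neighbour graph over cell indices 0..n-1."""

    n_cells: int
    edges: frozenset  # of (i, k) tuples with i < k

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        for i, k in self.edges:
            deg[i] += 1
            deg[k] += 1
        return deg

    def edge_array(self) -> np.ndarray:
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.edges), dtype=int)


@dataclass
class NeighbourhoodStats:
    """Per-centre-type neighbour composition.

    ``composition[j]`` holds the proportions of neighbour types around
    type-j centres (NaN where undefined, flagged in ``row_defined``);
    ``counts`` carries the underlying pooled integer tallies.
    """

    counts: np.ndarray                  # (4, 4) int
    composition: np.ndarray             # (4, 4) float, rows sum to 1 or NaN
    row_defined: np.ndarray             # (4,) bool
    n_cells: int = 0
    per_organoid: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.composition, index=TYPE_NAMES,
                            columns=TYPE_NAMES)


def delaunay_adjacency(positions, max_edge_length: float | None = None) -> AdjacencyGraph:
    """Neighbour graph from the 3D Delaunay triangulation of ``positions``.

    ``max_edge_length`` optionally drops edges longer than that length
    (guards against sliver edges across the convex hull; off by default).
    Degenerate input (coplanar points, or fewer than 4) raises
    :class:`DegenerateInputError`; the caller may jitter and retry.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    n = pos.shape[0]
    if n < 4:
        raise DegenerateInputError(
            f"3D triangulation needs at least 4 points, got {n}")
    try:
        tri = Delaunay(pos)
    except QhullError as e:
        raise DegenerateInputError(
            f"degenerate (coplanar or coincident) input: {e}") from e
    if tri.simplices.shape[1] != 4:
        raise DegenerateInputError("input is not full-dimensional in 3D")
    edges = set()
    s = tri.simplices
    for a in range(4):
        for b in range(a + 1, 4):
            for i, k in zip(s[:, a], s[:, b]):
                edges.add((min(i, k), max(i, k)))
    if max_edge_length is not None:
        edges = {
            (i, k) for i, k in edges
            if np.linalg.norm(pos[i] - pos[k]) <= max_edge_length
        }
    return AdjacencyGraph(n_cells=n, edges=frozenset(
        (int(i), int(k)) for i, k in edges))


def neighbourhood_composition(etypes, graph: AdjacencyGraph,
                              per_cell_mean: bool = False) -> NeighbourhoodStats:
    """Neighbour-type composition per centre type.

    Default: pooled neighbour multiset per centre type, then normalised.
    ``per_cell_mean=True`` instead averages each centre cell's own neighbour
    proportion vector (sensitivity-analysis variant).  Centre types with no
    cells (or no neighbours) yield an undefined, NaN-filled row flagged in
    ``row_defined``.
    """
    codes = etype_codes(etypes)
    if codes.shape[0] != graph.n_cells:
        raise ValueError("etypes length does not match graph size")
    if np.any(codes < 0):
        raise ValueError("all cells must have an assigned expression type")
    counts = np.zeros((N_TYPES, N_TYPES), dtype=np.int64)
    ea = graph.edge_array()
    if ea.size:
        ti, tk = codes[ea[:, 0]], codes[ea[:, 1]]
        np.add.at(counts, (ti, tk), 1)
        np.add.at(counts, (tk, ti), 1)
    if per_cell_mean:
        comp = np.full((N_TYPES, N_TYPES), np.nan)
        per_cell = np.zeros((graph.n_cells, N_TYPES))
        deg = graph.degrees()
        if ea.size:
            np.add.at(per_cell, (ea[:, 0], codes[ea[:, 1]]), 1)
            np.add.at(per_cell, (ea[:, 1], codes[ea[:, 0]]), 1)
        with np.errstate(invalid="ignore"):
            per_cell = per_cell / deg[:, None]
        for j in range(N_TYPES):
            rows = per_cell[(codes == j) & (deg > 0)]
            if rows.size:
                comp[j] = rows.mean(axis=0)
        row_defined = ~np.isnan(comp[:, 0])
    else:
        totals = counts.sum(axis=1)
        row_defined = totals > 0
        comp = np.full((N_TYPES, N_TYPES), np.nan)
        comp[row_defined] = counts[row_defined] / totals[row_defined, None]
    return NeighbourhoodStats(counts=counts, composition=comp,
                              row_defined=row_defined, n_cells=graph.n_cells)


def effect_size_psi(sim: NeighbourhoodStats | np.ndarray,
                    exp: NeighbourhoodStats | np.ndarray) -> tuple[float, dict]:
    """Mean relative deviation |s - m| / m over composition entries.

    Entries whose reference value m is zero (or undefined) cannot be used as
    denominators; they are excluded from the mean and reported in the
    returned metadata rather than divided through.
    """
    s = sim.composition if isinstance(sim, NeighbourhoodStats) else np.asarray(sim, float)
    m = exp.composition if isinstance(exp, NeighbourhoodStats) else np.asarray(exp, float)
    if s.shape != m.shape:
        raise ValueError("composition matrices must share a shape")
    valid = np.isfinite(s) & np.isfinite(m) & (m > 0)
    excluded = [(TYPE_NAMES[i], TYPE_NAMES[k]) if s.shape == (N_TYPES, N_TYPES)
                else (int(i), int(k))
                for i, k in zip(*np.nonzero(~valid))]
    if not np.any(valid):
        raise ValueError("no valid entries: all reference proportions are zero")
    psi = float(np.mean(np.abs(s[valid] - m[valid]) / m[valid]))
    meta = {"aggregation": "entrywise |s-m|/m averaged over defined entries",
            "n_entries": int(valid.sum()), "excluded_entries": excluded}
    return psi, meta


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p, normal approximation with tie correction."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue)


def compare_compositions(simset, expset, alpha: float = 0.05,
                         n_tests: int | None = None) -> pd.DataFrame:
    """Entrywise rank-sum comparison of two sets of composition replicates.

    ``simset``/``expset`` are lists of :class:`NeighbourhoodStats` (one per
    simulation run / per organoid).  Each of the 16 (centre, neighbour)
    entries is tested two-sided on the per-replicate proportions; Bonferroni
    adjusts by the number of comparisons actually performed unless
    ``n_tests`` overrides it.
    """
    sim = np.array([s.composition for s in simset])
    exp = np.array([s.composition for s in expset])
    rows = []
    for j in range(N_TYPES):
        for t in range(N_TYPES):
            x = sim[:, j, t]
            y = exp[:, j, t]
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if len(x) < 2 or len(y) < 2:
                rows.append((TYPE_NAMES[j], TYPE_NAMES[t], len(x), len(y),
                             np.nan))
                continue
            rows.append((TYPE_NAMES[j], TYPE_NAMES[t], len(x), len(y),
                         _ranksum_p(x, y)))
    report = pd.DataFrame(rows, columns=["centre", "neighbour", "n_sim",
                                         "n_exp", "p_raw"])
    performed = int(report["p_raw"].notna().sum())
    factor = performed if n_tests is None else int(n_tests)
    report["p_adj"] = np.minimum(1.0, report["p_raw"] * factor)
    report["significant"] = report["p_adj"] < alpha
    report.attrs["bonferroni_factor"] = factor
    report.attrs["alpha"] = alpha
    return report


def same_type_enrichment(stats: NeighbourhoodStats, baseline_proportions) -> np.ndarray:
    """Diagonal composition minus global proportion, per type.

    Positive values mean cells of that type see more same-type neighbours
    than expected under random mixing; ~0 means random mixing.  Undefined
    composition rows propagate as NaN entries.
    """
    p = as_proportions(baseline_proportions)
    return np.diagonal(stats.composition) - p
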