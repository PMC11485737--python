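"""Pairwise-correlation functional networks, degree ranking, stability.

The functional similarity of two neurons is the Pearson correlation of
their dF/F0 series over the analysis window,

    rho(A, B) = 1/(N-1) * sum_i ((A_i - mu_A)/sigma_A) * ((B_i - mu_B)/sigma_B).

Two pruning schemes turn the correlation matrix into a graph: a minimum
spanning tree over edge weights w = 1 - |rho| (keeps every neuron, picks
the N-1 strongest links without cycles), or a simple threshold on |rho|.
Neurons are ranked by degree; the top-ranked cells are the candidates for
display and photostimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "FunctionalGraph",
    "pairwise_correlations",
    "mst_network",
    "threshold_network",
    "rank_by_degree",
    "ranking_stability",
]

DEFAULT_MIN_SAMPLES = 30


class WindowTooShortError(ValueError):
    """Analysis window holds fewer than min_samples usable frames."""


@dataclass(frozen=True)
class CorrelationMatrix:
    rho: np.ndarray  # (n, n), NaN where undefined (zero-variance trace)
    cell_ids: list[int]
    window: tuple[int, int]  # (start_frame, end_frame), end exclusive

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class FunctionalGraph:
    cell_ids: list[int]
    edges: list[tuple[int, int, float, float]]  # (cell_i, cell_j, rho, weight)
    method: str  # "mst" | "threshold"
    degree: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degree:
            self.degree = {c: 0 for c in self.cell_ids}
            for i, j, _, _ in self.edges:
                self.degree[i] += 1
                self.degree[j] += 1

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["cell_i", "cell_j", "rho", "weight"])


def pairwise_correlations(
    dff_window: np.ndarray,
    cell_ids: list[int] | None = None,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    window: tuple[int, int] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation matrix over a (frames, cells) dF/F0 window.

    Frames with any non-finite entry are dropped so all pairs share one
    sample set.  Zero-variance traces yield NaN rows/columns (undefined
    correlations).  Raises WindowTooShortError below ``min_samples`` usable
    frames.
    """
    x = np.asarray(dff_window, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("dff_window must be (frames, cells)")
    n_cells = x.shape[1]
    if cell_ids is None:
        cell_ids = list(range(n_cells))
    keep = np.all(np.isfinite(x), axis=1)
    x = x[keep]
    n = x.shape[0]
    if n < min_samples:
        raise WindowTooShortError(
            f"{n} usable frames < min_samples {min_samples}"
        )
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    ok = sd > 0
    z = np.zeros_like(x)
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    rho = (z.T @ z) / (n - 1)
    rho[~ok, :] = np.nan
    rho[:, ~ok] = np.nan
    d = np.einsum("ii->i", rho)
    d[ok] = 1.0
    rho = np.clip(rho, -1.0, 1.0)
    if window is None:
        window = (0, int(dff_window.shape[0]))
    return CorrelationMatrix(rho=rho, cell_ids=list(cell_ids), window=window)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _edge_list(corr: CorrelationMatrix):
    """All pairs as (weight, min_id, max_id, rho); undefined rho -> weight 1."""
    edges = []
    ids = corr.cell_ids
    for a in range(corr.n_cells):
        for b in range(a + 1, corr.n_cells):
            r = corr.rho[a, b]
            w = 1.0 if np.isnan(r) else 1.0 - abs(r)
            i, j = sorted((ids[a], ids[b]))
            edges.append((w, i, j, float(r) if np.isfinite(r) else np.nan))
    return edges


def mst_network(corr: CorrelationMatrix) -> FunctionalGraph:
    """Minimum spanning tree of the complete graph with w = 1 - |rho|.

    Kruskal with edges pre-sorted by (weight, min_id, max_id) for
    deterministic tie-breaking; undefined correlations enter with weight 1
    so flat cells connect last but are never dropped.  Fewer than two
    usable nodes yield an empty graph.
    """
    if corr.n_cells < 2:
        return FunctionalGraph(cell_ids=list(corr.cell_ids), edges=[], method="mst")
    edges = sorted(_edge_list(corr), key=lambda e: (e[0], e[1], e[2]))
    uf = _UnionFind(corr.cell_ids)
    kept = []
    for w, i, j, r in edges:
        if uf.union(i, j):
            kept.append((i, j, r, w))
            if len(kept) == corr.n_cells - 1:
                break
    return FunctionalGraph(cell_ids=list(corr.cell_ids), edges=kept, method="mst")


def threshold_network(corr: CorrelationMatrix, theta: float) -> FunctionalGraph:
    """Keep pairs with |rho| >= theta; isolated nodes stay with degree 0.

    Undefined correlations never pass the threshold.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    kept = [
        (i, j, r, w)
        for w, i, j, r in _edge_list(corr)
        if np.isfinite(r) and abs(r) >= theta
    ]
    return FunctionalGraph(cell_ids=list(corr.cell_ids), edges=kept, method="threshold")


def rank_by_degree(graph: FunctionalGraph) -> list[int]:
    """Cell ids sorted by (degree descending, cell_id ascending).

    The head of the list — by convention the top five — marks the
    automatic display/stimulation candidates.
    """
    return sorted(graph.cell_ids, key=lambda c: (-graph.degree[c], c))


def ranking_stability(ranking_series: list[list[int]], k: int = 10) -> float:
    """Mean percent turnover of the top-k set between adjacent rankings.

    For each adjacent pair of rankings, percent = 100 * |set difference of
    the two top-k sets| / k; returns the mean over pairs.  0 means the
    top-k membership never changes, 100 means it is disjoint at every step.
    """
    if len(ranking_series) < 2:
        raise ValueError("need at least two successive rankings")
    changes = []
    for prev, cur in zip(ranking_series[:-1], ranking_series[1:]):
        a, b = set(prev[:k]), set(cur[:k])
        changes.append(100.0 * len(a - b) / k)
    return float(np.mean(changes))
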