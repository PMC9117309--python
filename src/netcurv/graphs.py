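"""Nested binarized graph series via maximum spanning tree + sparsity thresholding.

For each subject the MST of the correlation matrix is built first
(Kruskal with deterministic tie-breaking), then edges are added in
decreasing order of correlation until each target density's edge budget
is reached.  Every graph in the series is therefore connected, contains
the MST, and the series is nested across the density grid.

Edge budgets are computed exactly: densities are carried as rationals so
that round-half-even of ``d * n(n-1)/2`` never depends on binary
floating-point representation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction

import networkx as nx
import numpy as np

from .connectivity import FCMatrix
from .errors import ConfigurationError, InputError

Edge = tuple[int, int]


def _to_fraction(x: float | str | Fraction) -> Fraction:
    if isinstance(x, Fraction):
        return x
    # limit_denominator recovers the intended decimal (grids are specified
    # to a few decimal places) from its float representation
    return Fraction(x).limit_denominator(10**9)


@dataclass(frozen=True)
class DensityGrid:
    """Inclusive arithmetic grid of graph densities.

    The default grid (0.02 to 0.50, step 0.01) has exactly 49 values.
    """

    start: float = 0.02
    stop: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        s, e, h = map(_to_fraction, (self.start, self.stop, self.step))
        if not (0 < s <= e < 1):
            raise ConfigurationError(
                f"need 0 < start <= stop < 1, got start={self.start}, stop={self.stop}"
            )
        if h <= 0:
            raise ConfigurationError(f"step must be positive, got {self.step}")

    @property
    def fractions(self) -> list[Fraction]:
        s, e, h = map(_to_fraction, (self.start, self.stop, self.step))
        k = int((e - s) / h)
        return [s + i * h for i in range(k + 1)]

    @property
    def values(self) -> list[float]:
        return [float(d) for d in self.fractions]

    def __len__(self) -> int:
        return len(self.fractions)

    def edge_budget(self, density: Fraction, n_nodes: int) -> int:
        """round-half-even(d * n(n-1)/2), computed on exact rationals."""
        m = n_nodes * (n_nodes - 1) // 2
        return round(density * m)


def _sorted_edges(fc: FCMatrix) -> list[tuple[float, int, int]]:
    """All off-diagonal edges as (weight, i, j), i<j, in deterministic
    decreasing-weight order with lexicographic (i, j) tie-break."""
    n = fc.n_rois
    iu, ju = np.triu_indices(n, k=1)
    w = fc.matrix[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return [(float(w[k]), int(iu[k]), int(ju[k])) for k in order]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def max_spanning_tree(fc: FCMatrix, rank_by: str = "signed") -> frozenset[Edge]:
    """Kruskal maximum spanning tree over the off-diagonal correlations.

    Returns the n-1 tree edges as 0-based (i, j) index pairs, i < j.
    Deterministic: ties are broken lexicographically on the index pair.
    """
    n = fc.n_rois
    if n < 2:
        raise InputError(f"need >= 2 ROIs for a spanning tree, got {n}")
    edges = _rank_edges(fc, rank_by)
    uf = _UnionFind(n)
    tree: list[Edge] = []
    for _, i, j in edges:
        if uf.union(i, j):
            tree.append((i, j))
            if len(tree) == n - 1:
                break
    return frozenset(tree)


def _rank_edges(fc: FCMatrix, rank_by: str) -> list[tuple[float, int, int]]:
    if rank_by not in ("signed", "absolute"):
        raise ConfigurationError(f"rank_by must be 'signed' or 'absolute', got {rank_by!r}")
    edges = _sorted_edges(fc)
    if rank_by == "absolute":
        edges = sorted(edges, key=lambda e: (-abs(e[0]), e[1], e[2]))
    return edges


@dataclass
class GraphSeries:
    """Nested sequence of binarized graphs for one subject across a grid."""

    subject_id: str
    n_nodes: int
    mst_edges: frozenset[Edge]
    graphs: list[tuple[float, frozenset[Edge]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def densities(self) -> list[float]:
        return [d for d, _ in self.graphs]

    def to_networkx(self, index: int) -> nx.Graph:
        _, edges = self.graphs[index]
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(edges)
        return g


def build_graph_series(
    fc: FCMatrix, grid: DensityGrid | None = None, rank_by: str = "signed"
) -> GraphSeries:
    """Construct the nested graph series for one subject.

    Edges beyond the MST are the globally highest-correlation non-MST
    edges; weights are then discarded (binarization).
    """
    if grid is None:
        grid = DensityGrid()
    n = fc.n_rois
    mst = max_spanning_tree(fc, rank_by=rank_by)
    ranked = _rank_edges(fc, rank_by)
    extra = [(i, j) for _, i, j in ranked if (i, j) not in mst]

    fracs = grid.fractions
    min_budget = grid.edge_budget(fracs[0], n)
    if min_budget < n - 1:
        # smallest feasible density keeps budget >= n-1 (the MST size)
        m = n * (n - 1) // 2
        feasible = Fraction(n - 1, m)
        raise ConfigurationError(
            f"edge budget {min_budget} at density {float(fracs[0])} is below the "
            f"MST size {n - 1}; minimum feasible density is {float(feasible):.6g}"
        )

    ordered = sorted(mst) + extra  # MST first, then ranked extras
    graphs: list[tuple[float, frozenset[Edge]]] = []
    for d in fracs:
        k = grid.edge_budget(d, n)
        graphs.append((float(d), frozenset(ordered[:k])))
    return GraphSeries(fc.subject_id, n, mst, graphs)


def write_edge_lists(series: GraphSeries, out_dir, roi_ids: list[int] | None = None) -> dict:
    """Export each graph as a two-column TSV edge list (1-based ROI ids)
    plus a manifest JSON with edge counts and checksums."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    if roi_ids is None:
        roi_ids = list(range(1, series.n_nodes + 1))
    manifest = {"subject_id": series.subject_id, "n_nodes": series.n_nodes, "graphs": []}
    for density, edges in series.graphs:
        rows = sorted((roi_ids[i], roi_ids[j]) for i, j in edges)
        text = "\n".join(f"{u}\t{v}" for u, v in rows) + "\n"
        fname = f"{series.subject_id}_d{density:.4f}.tsv"
        path = os.path.join(out_dir, fname)
        with open(path, "w") as fh:
            fh.write(text)
        manifest["graphs"].append(
            {
                "density": density,
                "n_edges": len(rows),
                "file": fname,
                "sha256": hashlib.sha256(text.encode()).hexdigest(),
            }
        )
    mpath = os.path.join(out_dir, f"{series.subject_id}_manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
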