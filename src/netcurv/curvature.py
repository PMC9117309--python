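"""Forman-Ricci and Ollivier-Ricci edge curvature on unweighted graphs.

Edge FRC (classical): 4 - deg(u) - deg(v).
Edge FRC (augmented): 4 - deg(u) - deg(v) + 3 * #triangles(e).
Edge ORC: kappa(u, v) = 1 - W1(m_u, m_v) / d(u, v), where m_x places
mass alpha at x and (1 - alpha)/deg(x) on each neighbor, d is the
shortest-path hop metric, and W1 is the Wasserstein-1 distance solved
as an exact dense transportation linear program over the two supports.

Node curvature is the sum of incident edge curvatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class ORCConfig:
    """Idleness parameter for the ORC probability measure.

    alpha = 0 (default) is the non-lazy random walk: all mass spread
    uniformly over the neighbors.
    """

    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in [0, 1), got {self.alpha}")


FRC_VARIANTS = ("classical", "augmented")


def _check_edge(graph: nx.Graph, u, v) -> None:
    if not graph.has_edge(u, v):
        raise InputError(f"edge ({u}, {v}) not in graph")


def frc_edge(graph: nx.Graph, u, v, variant: str = "augmented") -> float:
    """Forman-Ricci curvature of one edge."""
    _check_edge(graph, u, v)
    if variant not in FRC_VARIANTS:
        raise ConfigurationError(f"unknown FRC variant {variant!r}")
    val = 4.0 - graph.degree(u) - graph.degree(v)
    if variant == "augmented":
        triangles = len(set(graph[u]) & set(graph[v]))
        val += 3.0 * triangles
    return val


def _measure(graph: nx.Graph, x, alpha: float) -> dict:
    deg = graph.degree(x)
    if deg == 0:
        raise InputError(f"node {x} has degree 0; ORC measure undefined")
    m = {nbr: (1.0 - alpha) / deg for nbr in graph[x]}
    if alpha > 0.0:
        m[x] = m.get(x, 0.0) + alpha
    return m


def _support_distances(graph: nx.Graph, sources, targets) -> np.ndarray:
    """Hop-count distances from each source to each target via BFS."""
    t_index = {t: k for k, t in enumerate(targets)}
    D = np.full((len(sources), len(targets)), np.inf)
    for i, s in enumerate(sources):
        dist = nx.single_source_shortest_path_length(graph, s)
        for t, k in t_index.items():
            if t in dist:
                D[i, k] = dist[t]
    if not np.isfinite(D).all():
        raise InputError("measure supports are disconnected; W1 undefined")
    return D


def wasserstein1(graph: nx.Graph, mu: dict, nu: dict) -> float:
    """Exact W1 between two finitely supported measures under hop distance.

    Solved as the dense transportation LP over the product of supports.
    """
    src = sorted(mu)
    dst = sorted(nu)
    D = _support_distances(graph, src, dst)
    a = np.array([mu[s] for s in src])
    b = np.array([nu[t] for t in dst])
    ns, nt = len(src), len(dst)
    # row-sum and column-sum equality constraints; drop the last row
    # (redundant since both measures sum to 1)
    A = np.zeros((ns + nt - 1, ns * nt))
    rhs = np.zeros(ns + nt - 1)
    for i in range(ns):
        A[i, i * nt : (i + 1) * nt] = 1.0
        rhs[i] = a[i]
    for j in range(nt - 1):
        A[ns + j, j::nt] = 1.0
        rhs[ns + j] = b[j]
    res = linprog(D.ravel(), A_eq=A, b_eq=rhs, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP on a valid instance always solves
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(res.fun)


def orc_edge(graph: nx.Graph, u, v, cfg: ORCConfig | None = None) -> float:
    """Ollivier-Ricci curvature of one edge: 1 - W1(m_u, m_v)."""
    _check_edge(graph, u, v)
    if cfg is None:
        cfg = ORCConfig()
    mu = _measure(graph, u, cfg.alpha)
    nu = _measure(graph, v, cfg.alpha)
    return 1.0 - wasserstein1(graph, mu, nu)


def edge_curvatures(
    graph: nx.Graph,
    kind: str = "frc",
    variant: str = "augmented",
    cfg: ORCConfig | None = None,
) -> dict:
    """Curvature for every edge, keyed by the edge's sorted node pair."""
    if kind == "frc":
        return {
            _key(u, v): frc_edge(graph, u, v, variant) for u, v in graph.edges()
        }
    if kind == "orc":
        return {_key(u, v): orc_edge(graph, u, v, cfg) for u, v in graph.edges()}
    raise ConfigurationError(f"kind must be 'frc' or 'orc', got {kind!r}")


def _key(u, v):
    return (u, v) if u <= v else (v, u)


def node_curvature(edge_table: dict, graph: nx.Graph) -> dict:
    """Node curvature = sum of incident edge curvatures (exact identity)."""
    out = {n: 0.0 for n in graph.nodes()}
    for u, v in graph.edges():
        k = _key(u, v)
        if k not in edge_table:
            raise InputError(f"edge table missing value for edge {k}")
        out[u] += edge_table[k]
        out[v] += edge_table[k]
    return out


def average_edge_curvature(edge_table: dict) -> float:
    if not edge_table:
        raise InputError("empty edge set: average curvature undefined")
    return float(np.mean(list(edge_table.values())))
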