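"""Standard global and nodal measures on connected binarized graphs.

All definitions are the standard binary ones (NetworkX implementations):
Watts-Strogatz clustering, greedy modularity maximization, hop-count
shortest paths, normalized betweenness, global efficiency, and local
efficiency over open neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class GlobalMeasures:
    avg_clustering: float
    modularity: float
    avg_shortest_path: float
    avg_node_betweenness: float
    global_efficiency: float
    avg_local_efficiency: float

    FIELDS = (
        "avg_clustering",
        "modularity",
        "avg_shortest_path",
        "avg_node_betweenness",
        "global_efficiency",
        "avg_local_efficiency",
    )

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


@dataclass(frozen=True)
class NodalMeasures:
    clustering: dict
    betweenness: dict


def _require_connected(graph: nx.Graph) -> None:
    if graph.number_of_nodes() < 3:
        raise InputError("need >= 3 nodes")
    if not nx.is_connected(graph):
        raise InputError("graph must be connected")


def modularity_best_partition(graph: nx.Graph) -> tuple[float, list[set]]:
    """Modularity of the best partition found by greedy (CNM) maximization.

    The greedy optimizer is deterministic; the choice of optimizer is a
    configuration decision and other optimizers give different values.
    """
    communities = list(nx.community.greedy_modularity_communities(graph))
    q = nx.community.modularity(graph, communities)
    return float(q), communities


def global_measures(graph: nx.Graph) -> GlobalMeasures:
    _require_connected(graph)
    q, _ = modularity_best_partition(graph)
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    return GlobalMeasures(
        avg_clustering=float(nx.average_clustering(graph)),
        modularity=q,
        avg_shortest_path=float(nx.average_shortest_path_length(graph)),
        avg_node_betweenness=float(np.mean(list(betweenness.values()))),
        global_efficiency=float(nx.global_efficiency(graph)),
        avg_local_efficiency=float(nx.local_efficiency(graph)),
    )


def nodal_measures(graph: nx.Graph) -> NodalMeasures:
    _require_connected(graph)
    return NodalMeasures(
        clustering=dict(nx.clustering(graph)),
        betweenness=nx.betweenness_centrality(graph, normalized=True),
    )
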