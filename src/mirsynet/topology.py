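"""Global topology summary of an undirected network.

Five node-averaged statistics: average shortest path length, betweenness
centrality, closeness centrality, clustering coefficient and degree.
Conventions follow the common network-analyzer defaults: shortest paths
are unweighted and computed within connected components (pairs in
different components contribute nothing), betweenness is normalised by
(n-1)(n-2)/2 per component, closeness is the reciprocal of the mean
distance to reachable nodes, and the clustering coefficient of a node of
degree < 2 is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["TopologySummary", "global_topology"]


@dataclass
class TopologySummary:
    avg_shortest_path: float
    avg_betweenness: float
    avg_closeness: float
    avg_clustering_coefficient: float
    avg_degree: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "avg_shortest_path": self.avg_shortest_path,
                    "avg_betweenness": self.avg_betweenness,
                    "avg_closeness": self.avg_closeness,
                    "avg_clustering_coefficient": self.avg_clustering_coefficient,
                    "avg_degree": self.avg_degree,
                }
            ]
        )


def global_topology(graph: nx.Graph) -> TopologySummary:
    """Compute the five node-averaged topology statistics of ``graph``."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("graph is empty")

    path_sum = 0.0
    n_pairs = 0
    betweenness: dict = {}
    closeness: dict = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        nc = sub.number_of_nodes()
        if nc > 1:
            for _, dists in nx.all_pairs_shortest_path_length(sub):
                path_sum += sum(dists.values())
                n_pairs += len(dists) - 1
        # per-component normalisation: (nc-1)(nc-2)/2 pair baskets
        betweenness.update(nx.betweenness_centrality(sub, normalized=True))
        for node in comp:
            deg_sum = sum(nx.single_source_shortest_path_length(sub, node).values())
            closeness[node] = (nc - 1) / deg_sum if deg_sum > 0 else 0.0

    avg_path = path_sum / n_pairs if n_pairs else 0.0
    clustering = nx.clustering(graph)
    return TopologySummary(
        avg_shortest_path=avg_path,
        avg_betweenness=sum(betweenness.values()) / n,
        avg_closeness=sum(closeness.values()) / n,
        avg_clustering_coefficient=sum(clustering.values()) / n,
        avg_degree=2.0 * graph.number_of_edges() / n,
    )
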