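"""Node centrality for weighted signed symptom networks.

Four indices per node:

* **strength** — Σ_j |w_ij|;
* **expected influence (EI)** — Σ_j w_ij, the signed one-step sum over
  immediate neighbours (distinguishes negative from positive
  connectivity);
* **closeness** — 1 / Σ_j d(i, j) with edge length 1/|w_ij| (sum, not
  mean); a node with any unreachable partner, or no edges at all, gets
  closeness 0;
* **betweenness** — Brandes shortest-path counting on the same lengths,
  fractional on ties, summed over unordered pairs.

Edge sign is ignored for the path-based indices (standard in the
psychometric-network literature).  Each index is also reported
z-standardized across nodes (population SD); a constant index vector
standardizes to all zeros.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import Network, ValidationError

__all__ = ["centrality_table", "rank_nodes", "INDICES"]

INDICES = ("strength", "expected_influence", "closeness", "betweenness")


def _distance_graph(net: Network) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for s, t, w in net.edges():
        g.add_edge(s, t, length=1.0 / abs(w))
    return g


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population SD
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_table(net: Network) -> pd.DataFrame:
    """All four indices plus z-scores, indexed by node name."""
    if net.p < 2:
        raise ValidationError("centrality needs at least 2 nodes (z-scores undefined)")
    W = net.weights
    strength = np.abs(W).sum(axis=0)
    ei = W.sum(axis=0)

    g = _distance_graph(net)
    closeness = np.zeros(net.p)
    for i, node in enumerate(net.nodes):
        dist = nx.single_source_dijkstra_path_length(g, node, weight="length")
        if len(dist) == net.p:  # all partners reachable
            total = sum(d for other, d in dist.items() if other != node)
            closeness[i] = 1.0 / total if total > 0 else 0.0
    btw = nx.betweenness_centrality(g, weight="length", normalized=False)
    betweenness = np.array([btw[node] for node in net.nodes])

    table = pd.DataFrame(
        {
            "strength": strength,
            "expected_influence": ei,
            "closeness": closeness,
            "betweenness": betweenness,
        },
        index=pd.Index(net.nodes, name="node"),
    )
    for col in INDICES:
        table[f"z_{col}"] = _zscore(table[col].to_numpy())
    return table


def rank_nodes(table: pd.DataFrame, index: str, k: int) -> list[str]:
    """Top-k node names by a raw index; ties broken lexicographically by name."""
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}, got {index!r}")
    if k < 0:
        raise ValueError("k must be >= 0")
    order = sorted(table.index, key=lambda node: (-table.loc[node, index], node))
    return order[: min(k, len(order))]
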