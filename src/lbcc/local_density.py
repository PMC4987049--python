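"""Local neighborhood densities Den1 and Den2.

Den1(v) is the edge density of the subgraph induced by v's closed
neighborhood (v and its neighbors); Den2(v) is the edge density of the
subgraph induced by the closed ball of radius 2 around v (v, its neighbors,
and its neighbors' neighbors). Both lie in [0, 1]; an isolated node, for
which the density formula is 0/0, scores 0 so that every protein gets a
value. Den1 relates to the local clustering coefficient by
Den1(v) = ((|N_v| - 1) * LCC(v) + 2) / (|N_v| + 1) for degree >= 2.
"""

from __future__ import annotations

import networkx as nx

from .centrality_baselines import ScoreVector
from .graph_io import PPINetwork


def _induced_density(g: nx.Graph, nodes: set[str]) -> float:
    n = len(nodes)
    if n <= 1:
        return 0.0
    e = g.subgraph(nodes).number_of_edges()
    return 2.0 * e / (n * (n - 1))


def den1(net: PPINetwork) -> ScoreVector:
    """Density of the closed neighborhood G[N_v ∪ {v}].

    A degree-1 node scores 1.0 (its closed neighborhood is a single edge);
    Den1(v) = 1 exactly when the closed neighborhood induces a clique.
    """
    g = net.graph
    return ScoreVector(
        "DEN1", {v: _induced_density(g, set(g[v]) | {v}) for v in g.nodes})


def den2(net: PPINetwork) -> ScoreVector:
    """Density of the closed ball of radius 2 around v.

    The ball is built by breadth-first expansion to depth 2: v, every
    neighbor, and every neighbor-of-neighbor (which folds v and parts of N_v
    back in; the set union makes that immaterial).
    """
    g = net.graph
    out: dict[str, float] = {}
    for v in g.nodes:
        ball = {v} | set(g[v])
        for u in g[v]:
            ball |= set(g[u])
        out[v] = _induced_density(g, ball)
    return ScoreVector("DEN2", out)
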