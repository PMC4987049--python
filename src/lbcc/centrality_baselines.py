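"""Classical node-centrality measures used as ranking baselines.

Implements degree (DC), betweenness (BC), subgraph (SC), eigenvector (EC),
local average connectivity (LAC), edge-clustering-based network centrality
(NC) and the local clustering coefficient (LCC) on an undirected simple PPI
graph. All measures are deterministic functions of the graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_io import ContractError, PPINetwork

#: node count above which the eigenvector solve switches from a dense
#: symmetric eigendecomposition to power iteration on a sparse matrix
_DENSE_EC_LIMIT = 3000


@dataclass(frozen=True)
class ScoreVector:
    """Per-protein values of one measure: name plus protein -> score map."""

    measure_name: str
    values: Mapping[str, float]

    def __post_init__(self):
        for pid, val in self.values.items():
            if not math.isfinite(val):
                raise ContractError(
                    f"{self.measure_name}: non-finite score for {pid!r}")

    def __getitem__(self, pid: str) -> float:
        return self.values[pid]

    def __len__(self) -> int:
        return len(self.values)


def degree_centrality(net: PPINetwork) -> ScoreVector:
    """DC(v) = number of neighbors of v (raw degree, not normalized)."""
    return ScoreVector("DC", {v: float(d) for v, d in net.graph.degree()})


def betweenness_centrality(net: PPINetwork, ordered_pairs: bool = False) -> ScoreVector:
    """Unnormalized shortest-path betweenness with endpoints excluded.

    BC(v) sums, over unordered node pairs {s, t} with s, t != v in v's
    component, the fraction of s-t shortest paths through v (Brandes
    accumulation; unreachable pairs contribute nothing). Set
    ``ordered_pairs=True`` to count each pair in both directions (exactly
    doubles every value), matching tools that use the directed convention.
    """
    bc = nx.betweenness_centrality(net.graph, normalized=False)
    factor = 2.0 if ordered_pairs else 1.0
    return ScoreVector("BC", {v: factor * val for v, val in bc.items()})


def subgraph_centrality(net: PPINetwork) -> ScoreVector:
    """SC(v) = sum over k of (closed walks of length k at v) / k!.

    Computed spectrally: SC(v) = sum_j u_j[v]^2 * exp(lambda_j) over the
    eigenpairs of the adjacency matrix, evaluated per connected component so
    the dense solve stays small. An isolated node scores 1 (the length-0 walk).
    """
    g = net.graph
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            out[nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
        lam, u = np.linalg.eigh(a)
        sc = (u ** 2) @ np.exp(lam)
        for node, val in zip(nodes, sc):
            out[node] = float(val)
    return ScoreVector("SC", out)


def eigenvector_centrality(net: PPINetwork) -> ScoreVector:
    """Component of the principal adjacency eigenvector, non-negative, ||.||_2 = 1.

    Dense symmetric eigensolve up to 3000 nodes; power iteration (tolerance
    1e-12, max 10000 iterations) above. Requires at least one edge.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ContractError("eigenvector centrality undefined on an edgeless graph")
    nodes = sorted(g.nodes)
    if len(nodes) <= _DENSE_EC_LIMIT:
        a = nx.to_numpy_array(g, nodelist=nodes)
        lam, u = np.linalg.eigh(a)
        vec = u[:, -1]
    else:
        a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float)
        vec = _power_iteration(a)
    # principal eigenvector of a connected non-negative matrix has one sign;
    # across components, take magnitudes so the convention is entrywise >= 0
    vec = np.abs(vec)
    vec /= np.linalg.norm(vec)
    return ScoreVector("EC", {n: float(x) for n, x in zip(nodes, vec)})


def _power_iteration(a: sp.sparray, tol: float = 1e-12, max_iter: int = 10000) -> np.ndarray:
    n = a.shape[0]
    x = np.full(n, 1.0 / math.sqrt(n))
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ContractError("power iteration hit the zero vector")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    return x


def lac(net: PPINetwork) -> ScoreVector:
    """Local average connectivity: mean degree of v's neighbors within G[N_v].

    LAC(v) = (1/|N_v|) * sum over u in N_v of u's degree in the subgraph
    induced by N_v alone (v excluded); 0 for isolated nodes.
    """
    g = net.graph
    out: dict[str, float] = {}
    for v in g.nodes:
        nbrs = set(g[v])
        if not nbrs:
            out[v] = 0.0
            continue
        internal_deg_sum = sum(1 for u in nbrs for w in g[u] if w in nbrs)
        out[v] = internal_deg_sum / len(nbrs)
    return ScoreVector("LAC", out)


def nc(net: PPINetwork) -> ScoreVector:
    """Network centrality: sum of edge clustering coefficients over v's edges.

    For each edge (u, v), ECC(u, v) = z(u, v) / min(deg(u) - 1, deg(v) - 1)
    with z the number of common neighbors; ECC is 0 when the denominator is 0.
    NC(v) sums ECC over all edges incident to v, so it vanishes on
    triangle-free graphs.
    """
    g = net.graph
    out: dict[str, float] = {v: 0.0 for v in g.nodes}
    for u, v in g.edges:
        denom = min(g.degree(u), g.degree(v)) - 1
        if denom <= 0:
            continue
        z = len(set(g[u]) & set(g[v]))
        ecc = z / denom
        out[u] += ecc
        out[v] += ecc
    return ScoreVector("NC", out)


def lcc(net: PPINetwork) -> ScoreVector:
    """Local clustering coefficient.

    With H the subgraph induced by v's closed neighborhood, |E(H)| counts v's
    |N_v| incident edges plus the edges among the neighbors, so
    2(|E(H)| - |N_v|) / (|N_v| (|N_v| - 1)) is the fraction of realized
    neighbor-neighbor edges. Nodes of degree <= 1 score 0.
    """
    g = net.graph
    out: dict[str, float] = {}
    for v in g.nodes:
        nbrs = set(g[v])
        k = len(nbrs)
        if k <= 1:
            out[v] = 0.0
            continue
        closed = nbrs | {v}
        e_h = g.subgraph(closed).number_of_edges()
        out[v] = 2.0 * (e_h - k) / (k * (k - 1))
    return ScoreVector("LCC", out)
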