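"""Independent brute-force oracles used to verify the fast implementations.

These deliberately avoid the code paths they check: betweenness by explicit
enumeration of all shortest paths, subgraph centrality by the truncated
closed-walk series via repeated matrix multiplication, and the densities by
explicit node-set construction with pairwise edge counting.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np


def brute_betweenness(g: nx.Graph, v) -> float:
    """Sum over unordered pairs {s,t} (endpoints excluded) of the fraction
    of s-t shortest paths through v, by explicit path enumeration."""
    total = 0.0
    for s, t in combinations(g.nodes, 2):
        if s == v or t == v or not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total


def walk_series_sc(g: nx.Graph, max_k: int = 20) -> dict:
    """Subgraph centrality by the truncated series sum_k (A^k)_vv / k!."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    power = np.eye(len(nodes))
    diag_sum = np.zeros(len(nodes))
    for k in range(max_k + 1):
        diag_sum += np.diag(power) / math.factorial(k)
        power = power @ a
    return dict(zip(nodes, diag_sum))


def _density_of(nodeset: set, edges: set[frozenset]) -> float:
    n = len(nodeset)
    if n <= 1:
        return 0.0
    e = sum(1 for u, w in combinations(sorted(nodeset), 2)
            if frozenset((u, w)) in edges)
    return 2.0 * e / (n * (n - 1))


def brute_den1(g: nx.Graph, v) -> float:
    edges = {frozenset(e) for e in g.edges}
    return _density_of(set(g[v]) | {v}, edges)


def brute_den2(g: nx.Graph, v) -> float:
    edges = {frozenset(e) for e in g.edges}
    ball = {v}
    frontier = {v}
    for _ in range(2):
        frontier = {w for u in frontier for w in g[u]} - ball
        ball |= frontier
    return _density_of(ball, edges)


def random_ppi_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Seeded G(n, p) with string protein-style labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
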