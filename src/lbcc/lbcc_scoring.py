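"""The combined LBCC score and its protein-complex ingredient IDC.

LBCC(v) = a·log Den1(v) + b·log Den2(v) + c·log IDC(v) + d·log BC(v),
with default weights (a, b, c, d) = (1, 4, 3, 1). IDC(v) is the sum, over
the complexes containing v, of v's PPI degree restricted to each complex's
members; a protein in no complex is assigned the floor 0.001. The same
floor is applied to every factor before the logarithm so that leaves
(BC = 0) and isolated proteins keep finite scores. Rankings are invariant
to the log base, so the base (default e) only rescales absolute values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .centrality_baselines import ScoreVector
from .graph_io import ComplexCollection, ContractError, PPINetwork


@dataclass(frozen=True)
class LBCCWeights:
    """Scaling weights for the four log terms, each restricted to [0, 10]."""

    a: float = 1.0
    b: float = 4.0
    c: float = 3.0
    d: float = 1.0
    floor_value: float = 0.001
    log_base: float = math.e

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            w = getattr(self, name)
            if not 0.0 <= w <= 10.0:
                raise ContractError(f"weight {name}={w} outside [0, 10]")
        if self.floor_value <= 0:
            raise ContractError("floor_value must be positive")
        if self.log_base <= 0 or self.log_base == 1:
            raise ContractError("log_base must be positive and != 1")


@dataclass(frozen=True)
class RankedPrediction:
    """Descending-score ordering with ties broken by ascending identifier."""

    ordering: tuple[str, ...]
    scores: ScoreVector

    def top(self, k: int) -> tuple[str, ...]:
        if k > len(self.ordering):
            raise ContractError(f"k={k} exceeds ranking length {len(self.ordering)}")
        return self.ordering[:k]

    def __len__(self) -> int:
        return len(self.ordering)


def idc(net: PPINetwork, complexes: ComplexCollection,
        floor_value: float = 0.001) -> ScoreVector:
    """In-degree centrality of complex.

    For each complex containing v, count v's PPI neighbors that are also
    members of that complex, and sum over complexes. Proteins in no complex —
    and proteins whose in-complex degree sums to zero — get ``floor_value``
    so the downstream logarithm is defined. Complex members absent from the
    network contribute nothing.
    """
    g = net.graph
    totals: dict[str, float] = {v: 0.0 for v in g.nodes}
    for _cid, members in complexes:
        present = {m for m in members if m in totals}
        for v in present:
            totals[v] += sum(1 for u in g[v] if u in present)
    return ScoreVector(
        "IDC", {v: (t if t > 0 else floor_value) for v, t in totals.items()})


def lbcc(den1: ScoreVector, den2: ScoreVector, idc_scores: ScoreVector,
         bc: ScoreVector, weights: LBCCWeights = LBCCWeights()) -> ScoreVector:
    """Weighted log-combination of Den1, Den2, IDC and betweenness.

    Every factor is floored at ``weights.floor_value`` before taking the log,
    so all outputs are finite. All four vectors must cover the same node set
    and be non-negative.
    """
    node_set = set(den1.values)
    for sv in (den2, idc_scores, bc):
        if set(sv.values) != node_set:
            raise ContractError(
                f"LBCC inputs cover different node sets ({den1.measure_name} "
                f"vs {sv.measure_name})")
    for sv in (den1, den2, idc_scores, bc):
        neg = [p for p, x in sv.values.items() if x < 0]
        if neg:
            raise ContractError(
                f"negative {sv.measure_name} score for {neg[0]!r}")
    w, floor = weights, weights.floor_value
    ln_base = math.log(weights.log_base)

    def term(coef: float, x: float) -> float:
        return coef * math.log(max(x, floor)) / ln_base

    values = {
        v: (term(w.a, den1.values[v]) + term(w.b, den2.values[v])
            + term(w.c, idc_scores.values[v]) + term(w.d, bc.values[v]))
        for v in node_set
    }
    return ScoreVector("LBCC", values)


def rank(scores: ScoreVector) -> RankedPrediction:
    """Deterministic ranking: descending score, ties by ascending identifier."""
    ordering = tuple(sorted(scores.values, key=lambda p: (-scores.values[p], p)))
    return RankedPrediction(ordering, scores)
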