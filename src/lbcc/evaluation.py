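"""Validation protocol for ranked essential-protein predictions.

Given a descending ranking and the set of known-essential proteins, this
module computes top-k true-essential counts, the confusion matrix at a
top-fraction cutoff, the six derived statistics (SN, SP, PPV, NPV, F, ACC),
precision–recall and jackknife (cumulative true positive) curves, and the
pairwise set-difference comparison of two methods' top-k predictions.
Proteins without essentiality annotation count as nonessential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .graph_io import ContractError, EssentialAnnotation
from .lbcc_scoring import RankedPrediction


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def p(self) -> int:
        """Number of essential proteins in the scored set."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Number of nonessential proteins in the scored set."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class StatReport:
    sn: float
    sp: float
    ppv: float
    npv: float
    f: float
    acc: float


@dataclass(frozen=True)
class CurveRow:
    rank: int
    cum_tp: int
    precision: float
    recall: float


@dataclass(frozen=True)
class CurveTable:
    rows: tuple[CurveRow, ...]

    def break_even(self) -> float | None:
        """Recall at the largest rank where precision >= recall, if any."""
        best = None
        for row in self.rows:
            if row.precision >= row.recall:
                best = row.recall
        return best


@dataclass(frozen=True)
class DifferenceSummary:
    """Set comparison of two methods' top-k predictions (A vs B)."""

    k: int
    common: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]
    essential_only_a: int
    essential_only_b: int


def top_k_true(pred: RankedPrediction, ess: EssentialAnnotation,
               ks: Sequence[int]) -> dict[int, int]:
    """Number of true essential proteins among the top k, for each k."""
    for k in ks:
        if k > len(pred):
            raise ContractError(f"k={k} exceeds ranking length {len(pred)}")
    counts = {}
    for k in ks:
        counts[k] = sum(1 for pid in pred.ordering[:k] if pid in ess)
    return counts


def confusion_at_fraction(pred: RankedPrediction, ess: EssentialAnnotation,
                          fraction: float = 0.2) -> ConfusionCounts:
    """Call the top floor(fraction * |ranking|) proteins essential, the rest not."""
    if not 0 < fraction < 1:
        raise ContractError(f"fraction must lie in (0, 1), got {fraction}")
    if len(pred) == 0:
        raise ContractError("cannot evaluate an empty ranking")
    k = int(fraction * len(pred))
    predicted = set(pred.ordering[:k])
    tp = fp = tn = fn = 0
    for pid in pred.ordering:
        essential = pid in ess
        called = pid in predicted
        if essential and called:
            tp += 1
        elif essential:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def statistics(c: ConfusionCounts) -> StatReport:
    """Sensitivity, specificity, predictive values, F-measure and accuracy."""
    if c.p == 0 or c.n == 0:
        raise ContractError(
            "statistics need at least one essential and one nonessential protein")
    sn = c.tp / c.p
    sp = c.tn / c.n
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    npv = c.tn / (c.tn + c.fn) if (c.tn + c.fn) else 0.0
    f = 2 * sn * ppv / (sn + ppv) if (sn + ppv) > 0 else 0.0
    acc = (c.tp + c.tn) / c.total
    return StatReport(sn=sn, sp=sp, ppv=ppv, npv=npv, f=f, acc=acc)


def pr_curve(pred: RankedPrediction, ess: EssentialAnnotation) -> CurveTable:
    """Precision TP(n)/n and recall TP(n)/P at every rank n."""
    p_total = sum(1 for pid in pred.ordering if pid in ess)
    if p_total == 0:
        raise ContractError("precision-recall curve needs >=1 essential protein")
    rows = []
    cum_tp = 0
    for n, pid in enumerate(pred.ordering, start=1):
        if pid in ess:
            cum_tp += 1
        rows.append(CurveRow(rank=n, cum_tp=cum_tp,
                             precision=cum_tp / n, recall=cum_tp / p_total))
    return CurveTable(tuple(rows))


def jackknife_curve(pred: RankedPrediction, ess: EssentialAnnotation) -> CurveTable:
    """Cumulative count of true essential proteins as a function of rank."""
    p_total = sum(1 for pid in pred.ordering if pid in ess)
    rows = []
    cum_tp = 0
    for n, pid in enumerate(pred.ordering, start=1):
        if pid in ess:
            cum_tp += 1
        rows.append(CurveRow(rank=n, cum_tp=cum_tp, precision=cum_tp / n,
                             recall=cum_tp / p_total if p_total else 0.0))
    return CurveTable(tuple(rows))


def method_difference(pred_a: RankedPrediction, pred_b: RankedPrediction,
                      ess: EssentialAnnotation, k: int) -> DifferenceSummary:
    """Compare two methods' top-k sets: overlap, exclusives, essentials therein."""
    set_a = frozenset(pred_a.top(k))
    set_b = frozenset(pred_b.top(k))
    only_a = set_a - set_b
    only_b = set_b - set_a
    return DifferenceSummary(
        k=k,
        common=set_a & set_b,
        only_a=only_a,
        only_b=only_b,
        essential_only_a=sum(1 for pid in only_a if pid in ess),
        essential_only_b=sum(1 for pid in only_b if pid in ess),
    )
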