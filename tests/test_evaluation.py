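import pytest
from hypothesis import given, settings, strategies as st

from lbcc import (ContractError, EssentialAnnotation, confusion_at_fraction,
                  jackknife_curve, method_difference, pr_curve, rank,
                  statistics, top_k_true)
from lbcc.evaluation import ConfusionCounts
from lbcc.centrality_baselines import ScoreVector


def ranking(ids):
    """RankedPrediction whose ordering is exactly *ids* (descending scores)."""
    n = len(ids)
    return rank(ScoreVector("m", {pid: float(n - i) for i, pid in enumerate(ids)}))


def ess(*ids):
    return EssentialAnnotation(frozenset(ids))


class TestTopK:
    def test_basic_counts(self):
        pred = ranking(["e1", "n1", "e2", "n2"])
        assert top_k_true(pred, ess("e1", "e2"), [2, 4]) == {2: 1, 4: 2}
        assert top_k_true(pred, ess(), [2]) == {2: 0}

    def test_k_too_large_is_error(self):
        with pytest.raises(ContractError):
            top_k_true(ranking(["a"]), ess("a"), [2])

    def test_monotone_in_k(self):
        pred = ranking([f"p{i}" for i in range(20)])
        labels = ess(*[f"p{i}" for i in range(0, 20, 3)])
        counts = top_k_true(pred, labels, list(range(1, 21)))
        values = [counts[k] for k in range(1, 21)]
        assert values == sorted(values)


class TestConfusion:
    def test_worked_counts(self):
        pred = ranking(["e1", "e2", "n1", "n2", "e3", "n3", "n4", "e4", "n5",
                        "n6"])
        c = confusion_at_fraction(pred, ess("e1", "e2", "e3", "e4"), 0.2)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 2, 6)

    def test_fraction_bounds_and_empty(self):
        pred = ranking(["a", "b"])
        with pytest.raises(ContractError):
            confusion_at_fraction(pred, ess("a"), 1.0)
        with pytest.raises(ContractError):
            confusion_at_fraction(ranking([]), ess("a"), 0.2)

    def test_no_essentials(self):
        c = confusion_at_fraction(ranking(["a", "b", "c", "d", "e"]), ess(), 0.4)
        assert c.tp == 0 and c.fn == 0 and c.total == 5


class TestStatistics:
    @pytest.mark.parametrize("counts, expected", [
        ((2, 0, 6, 2), (0.5, 1.0, 1.0, 0.75, 2 / 3, 0.8)),
        ((3, 1, 5, 1), (0.75, 5 / 6, 0.75, 5 / 6, 0.75, 0.8)),
    ])
    def test_direct_arithmetic(self, counts, expected):
        tp, fp, tn, fn = counts
        s = statistics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for got, want in zip((s.sn, s.sp, s.ppv, s.npv, s.f, s.acc), expected):
            assert got == pytest.approx(want)

    def test_degenerate_classes_rejected(self):
        with pytest.raises(ContractError):
            statistics(ConfusionCounts(tp=0, fp=1, tn=1, fn=0))  # P = 0
        with pytest.raises(ContractError):
            statistics(ConfusionCounts(tp=1, fp=0, tn=0, fn=1))  # N = 0


class TestCurves:
    def test_pr_rows(self):
        table = pr_curve(ranking(["e", "n"]), ess("e"))
        assert [(r.rank, r.cum_tp, r.precision, r.recall) for r in table.rows] \
            == [(1, 1, 1.0, 1.0), (2, 1, 0.5, 1.0)]

    def test_all_essential_and_worst_case(self):
        allk = pr_curve(ranking(["a", "b"]), ess("a", "b"))
        assert all(r.precision == 1.0 for r in allk.rows)
        worst = pr_curve(ranking(["n", "e"]), ess("e"))
        assert worst.rows[0].precision == 0.0

    def test_pr_requires_essentials(self):
        with pytest.raises(ContractError):
            pr_curve(ranking(["a"]), ess())

    def test_jackknife_cumulative(self):
        table = jackknife_curve(ranking(["e1", "n1", "e2"]), ess("e1", "e2"))
        assert [r.cum_tp for r in table.rows] == [1, 1, 2]
        zeros = jackknife_curve(ranking(["a", "b"]), ess())
        assert [r.cum_tp for r in zeros.rows] == [0, 0]

    def test_jackknife_equals_topk_everywhere(self):
        ids = [f"p{i:02d}" for i in range(15)]
        pred = ranking(ids)
        labels = ess(*ids[::4])
        table = jackknife_curve(pred, labels)
        counts = top_k_true(pred, labels, list(range(1, 16)))
        for row in table.rows:
            assert row.cum_tp == counts[row.rank]

    def test_break_even_point(self):
        # precision >= recall up to and including rank 2 (1.0 vs 0.5 then 1.0
        # vs 1.0), below recall afterwards
        table = pr_curve(ranking(["e1", "e2", "n1", "n2"]), ess("e1", "e2"))
        assert table.break_even() == pytest.approx(1.0)


class TestMethodDifference:
    def test_identical_and_disjoint(self):
        a = ranking(["p1", "p2", "p3", "p4"])
        b = ranking(["p3", "p4", "p1", "p2"])
        same = method_difference(a, a, ess("p1"), 2)
        assert len(same.common) == 2 and not same.only_a and not same.only_b
        disjoint = method_difference(a, b, ess("p1", "p3"), 2)
        assert len(disjoint.common) == 0
        assert disjoint.essential_only_a == 1  # p1 in A-B
        assert disjoint.essential_only_b == 1  # p3 in B-A

    def test_symmetry(self):
        a = ranking(["p1", "p2", "p3", "p4", "p5"])
        b = ranking(["p4", "p2", "p5", "p1", "p3"])
        labels = ess("p1", "p4")
        ab = method_difference(a, b, labels, 3)
        ba = method_difference(b, a, labels, 3)
        assert ab.only_a == ba.only_b and ab.only_b == ba.only_a
        assert ab.essential_only_a == ba.essential_only_b


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.booleans(), st.floats(0, 100, allow_nan=False)),
                min_size=5, max_size=60),
       st.floats(0.05, 0.95))
def test_confusion_conservation_on_random_rankings(rows, fraction):
    """TP+FP+TN+FN always equals the number of scored proteins, TP+FN the
    essential count, and the six statistics match direct formula evaluation."""
    ids = [f"p{i:03d}" for i in range(len(rows))]
    labels = ess(*[pid for pid, (is_ess, _) in zip(ids, rows) if is_ess])
    pred = rank(ScoreVector("m", {pid: score
                                  for pid, (_, score) in zip(ids, rows)}))
    c = confusion_at_fraction(pred, labels, fraction)
    assert c.total == len(ids)
    assert c.p == len(labels.essential_ids)
    assert c.n == len(ids) - len(labels.essential_ids)
    assert c.tp + c.fp == int(fraction * len(ids))
    if c.p and c.n:
        s = statistics(c)
        assert s.acc == pytest.approx((c.tp + c.tn) / len(ids))
        if s.sn + s.ppv > 0:
            assert s.f == pytest.approx(2 * s.sn * s.ppv / (s.sn + s.ppv))
    # PR / jackknife consistency: recall(n) * P == cumulative TP(n)
    if c.p:
        table = pr_curve(pred, labels)
        for row in table.rows:
            assert row.recall * c.p == pytest.approx(row.cum_tp)
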