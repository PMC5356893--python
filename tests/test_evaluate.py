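import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from crgpred.classify import ScorePair, predict
from crgpred.data_model import RECURRENT
from crgpred.evaluate import (
    ConfusionCounts,
    confusion_metrics,
    km_curve,
    logrank_test,
    roc_by_modifier,
)


class TestConfusionMetrics:
    def test_validation_cohort_counts(self):
        # 15 called recurrent of whom 12 recurred; 8 called non-recurrent
        # of whom 1 recurred
        m = confusion_metrics(ConfusionCounts(tp=12, fn=1, fp=3, tn=7))
        assert m["accuracy"] == pytest.approx(19 / 23)
        assert round(100 * m["accuracy"]) == 83
        assert round(100 * m["sensitivity"]) == 92
        assert m["specificity"] == pytest.approx(0.70)

    def test_all_ones(self):
        m = confusion_metrics(ConfusionCounts(1, 1, 1, 1))
        assert all(v == 0.5 for v in m.values())

    def test_perfect_ppv_when_no_false_positives(self):
        assert confusion_metrics(ConfusionCounts(5, 2, 0, 3))["ppv"] == 1.0

    def test_undefined_metric_is_none(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=3))
        assert m["sensitivity"] is None  # no true recurrences at all
        assert m["specificity"] == 0.6

    def test_from_predictions(self):
        predicted = {"a": RECURRENT, "b": RECURRENT, "c": "nonrecurrent"}
        truth = {"a": True, "b": False, "c": False}
        c = ConfusionCounts.from_predictions(predicted, truth)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 0, 1, 1)


def _pairs(margins):
    # encode arbitrary margins in non-negative score pairs
    base = max(1.0, 1 + max(abs(m) for m in margins))
    return [ScorePair(f"s{i}", base, base + m) for i, m in enumerate(margins)]


class TestRocByModifier:
    def test_perfect_separation(self):
        pairs = _pairs([2.0, 3.0, -1.0, -2.0])
        truth = {"s0": True, "s1": True, "s2": False, "s3": False}
        roc = roc_by_modifier(pairs, truth)
        assert roc.auc == pytest.approx(1.0)

    def test_two_sample_curve(self):
        pairs = _pairs([1.0, -1.0])
        truth = {"s0": True, "s1": False}
        roc = roc_by_modifier(pairs, truth)
        pts = {(fpr, tpr) for _, fpr, tpr in roc.points}
        assert {(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)} <= pts
        assert roc.auc == pytest.approx(1.0)

    def test_random_margins_auc_near_half(self):
        rng = np.random.default_rng(10)
        margins = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        pairs = _pairs(list(margins))
        truth = {f"s{i}": bool(b) for i, b in enumerate(labels)}
        roc = roc_by_modifier(pairs, truth)
        assert abs(roc.auc - 0.5) < 0.1

    def test_endpoints_and_monotone_fpr(self):
        rng = np.random.default_rng(3)
        pairs = _pairs(list(rng.normal(size=30)))
        truth = {f"s{i}": bool(rng.random() < 0.4) for i in range(30)}
        roc = roc_by_modifier(pairs, truth)
        fprs = [p[1] for p in roc.points]
        tprs = [p[2] for p in roc.points]
        assert (fprs[0], tprs[0]) == (0.0, 0.0)
        assert (fprs[-1], tprs[-1]) == (1.0, 1.0)
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    def test_tpr_at_zero_modifier_matches_base_sensitivity(self):
        rng = np.random.default_rng(8)
        pairs = _pairs(list(rng.normal(size=40)))
        truth = {f"s{i}": bool(rng.random() < 0.5) for i in range(40)}
        roc = roc_by_modifier(pairs, truth)
        base = {p.sample_id: predict(p) for p in pairs}
        c = ConfusionCounts.from_predictions(base, truth)
        sens = c.tp / (c.tp + c.fn)
        # modifier 0 need not be a change point; sensitivity at the largest
        # change point <= 0 equals base sensitivity
        tpr_at_0 = max(tpr for m, _, tpr in roc.points if m <= 0)
        assert tpr_at_0 == pytest.approx(sens)

    def test_auc_invariant_under_monotone_margin_transform(self):
        rng = np.random.default_rng(6)
        margins = rng.normal(size=25)
        truth = {f"s{i}": bool(rng.random() < 0.5) for i in range(25)}
        auc1 = roc_by_modifier(_pairs(list(margins)), truth).auc
        auc2 = roc_by_modifier(_pairs(list(np.tanh(margins))), truth).auc
        assert auc1 == pytest.approx(auc2)

    def test_matches_sklearn_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            margins = rng.normal(size=30)
            labels = rng.random(30) < 0.5
            if labels.all() or not labels.any():
                continue
            truth = {f"s{i}": bool(b) for i, b in enumerate(labels)}
            ours = roc_by_modifier(_pairs(list(margins)), truth).auc
            ref = roc_auc_score(labels, margins)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_by_modifier(_pairs([1.0, 2.0]), {"s0": True, "s1": True})


class TestKaplanMeier:
    def test_all_events_distinct_times(self):
        km = km_curve([1.0, 2.0, 3.0, 4.0], [True] * 4)
        assert [km.at(t) for t in (1, 2, 3, 4)] == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        km = km_curve([5.0, 8.0, 12.0], [False] * 3)
        assert km.at(12.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # events at 5 and 10, censored at 7: S(5)=2/3, S(10)=2/3 * 0 = 0
        km = km_curve([5.0, 7.0, 10.0], [True, False, True])
        assert km.at(5.0) == pytest.approx(2 / 3)
        assert km.at(10.0) == pytest.approx(0.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            km_curve([], [])

    def test_product_limit_identity_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = rng.integers(3, 12)
            times = np.round(rng.uniform(1, 30, n), 0) + 1
            events = rng.random(n) < 0.7
            km = km_curve(times, events)
            for t in np.unique(times):
                # direct product over event times <= t
                s = 1.0
                for u in np.unique(times[events & (times <= t)]):
                    d = int(np.sum(events & (times == u)))
                    at_risk = int(np.sum(times >= u))
                    s *= 1 - d / at_risk
                assert km.at(float(t)) == pytest.approx(s, abs=1e-9)


def _hand_logrank(ta, ea, tb, eb):
    """Independent O-E / hypergeometric-variance computation."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    all_t = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e, var = 0.0, 0.0
    for t in all_t:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        d1 = int(np.sum(ea & (ta == t)))
        d2 = int(np.sum(eb & (tb == t)))
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d1 - e1
        var += v
    return (o_minus_e ** 2) / var if var > 0 else 0.0


class TestLogrank:
    def test_identical_groups(self):
        t = [3.0, 6.0, 9.0]
        res = logrank_test(t, [True] * 3, t, [True] * 3)
        assert res["chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            na, nb = rng.integers(3, 10, 2)
            ta = np.round(rng.uniform(1, 40, na)) + 1
            tb = np.round(rng.uniform(1, 60, nb)) + 1
            ea = rng.random(na) < 0.8
            eb = rng.random(nb) < 0.8
            if not (ea.any() or eb.any()):
                continue
            res = logrank_test(ta, ea, tb, eb)
            assert res["chi_square"] == pytest.approx(
                _hand_logrank(ta, ea, tb, eb), abs=1e-9)

    def test_toy_statistic_is_permutation_extreme(self):
        # A events {1,2,3}, B events {4,5,6}: among all 20 assignments of
        # the six subjects into two groups of three, the observed split is
        # (jointly with its mirror) the most extreme by the log-rank
        # statistic -> exhaustive permutation p = 2/20
        from itertools import combinations
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        observed = logrank_test(times[:3], [True] * 3, times[3:], [True] * 3)
        stats = []
        for idx in combinations(range(6), 3):
            ta = [times[i] for i in idx]
            tb = [times[i] for i in range(6) if i not in idx]
            stats.append(_hand_logrank(ta, [True] * 3, tb, [True] * 3))
        n_ge = sum(s >= observed["chi_square"] - 1e-12 for s in stats)
        assert n_ge == 2  # observed split and its mirror
        assert observed["chi_square"] == pytest.approx(max(stats), abs=1e-9)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([5.0], [False], [6.0], [False])
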