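"""Exact matching, diagnostic-accuracy metrics and confidence intervals."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gbdmap.classifier import Classification
from gbdmap.evaluation import (
    NO_GBD,
    EvaluationError,
    GoldLabel,
    evaluate,
    exact_matching,
    load_gold,
    per_category_metrics,
    proportion_ci,
    save_gold,
    weighted_averages,
)


def _cls(tid, *cats):
    return Classification(tid, frozenset(cats))


def _gold(tid, *cats):
    return GoldLabel(tid, frozenset(cats))


class TestExactMatching:
    def test_identity_is_100_percent(self):
        gold = [_gold(f"T{i}", "a") for i in range(10)] + [_gold("T10"), _gold("T11", "a", "b")]
        pred = [_cls(g.trial_id, *g.categories) for g in gold]
        result = exact_matching(pred, gold)
        assert result.overall.proportion == 1.0

    def test_stratified_proportions(self):
        gold = [
            _gold("T1", "a"), _gold("T2", "a"), _gold("T3", "a"), _gold("T4", "b"),
            _gold("T5", "a", "b"),
            _gold("T6"),
        ]
        pred = [
            _cls("T1", "a"), _cls("T2", "a"), _cls("T3", "a"), _cls("T4", "a"),  # one miss
            _cls("T5", "a"),  # subset is a miss
            _cls("T6"),
        ]
        result = exact_matching(pred, gold)
        assert result.one_category.hits == 3 and result.one_category.n == 4
        assert result.one_category.proportion == 0.75
        assert result.two_or_more.hits == 0
        assert result.no_category.proportion == 1.0
        assert result.overall.n == 6

    def test_partial_overlap_is_a_miss(self):
        result = exact_matching([_cls("T1", "a")], [_gold("T1", "a", "b")])
        assert result.overall.hits == 0

    def test_unmatched_ids_rejected(self):
        with pytest.raises(EvaluationError, match="T2"):
            exact_matching([_cls("T1")], [_gold("T2")])


class TestPerCategoryMetrics:
    def _metrics(self, mini_grouping, tp, fp, tn, fn, cat="musculoskeletal"):
        pred, gold, i = [], [], 0
        for _ in range(tp):
            pred.append(_cls(f"T{i}", cat)); gold.append(_gold(f"T{i}", cat)); i += 1
        for _ in range(fp):
            pred.append(_cls(f"T{i}", cat)); gold.append(_gold(f"T{i}", "mental")); i += 1
        for _ in range(fn):
            pred.append(_cls(f"T{i}", "mental")); gold.append(_gold(f"T{i}", cat)); i += 1
        for _ in range(tn):
            pred.append(_cls(f"T{i}", "mental")); gold.append(_gold(f"T{i}", "mental")); i += 1
        out = per_category_metrics(pred, gold, mini_grouping)
        return next(m for m in out if m.category_id == cat)

    def test_textbook_counts(self, mini_grouping):
        m = self._metrics(mini_grouping, tp=8, fp=5, tn=85, fn=2)
        assert (m.tp, m.fp, m.tn, m.fn) == (8, 5, 85, 2)
        assert m.sensitivity == pytest.approx(0.80)
        assert m.specificity == pytest.approx(85 / 90)
        assert m.ppv == pytest.approx(8 / 13)
        assert m.lr_plus == pytest.approx(14.4)
        assert m.lr_minus == pytest.approx(0.2 / (85 / 90))

    def test_counts_sum_to_total(self, mini_grouping):
        m = self._metrics(mini_grouping, tp=3, fp=2, tn=10, fn=1)
        assert m.tp + m.fp + m.tn + m.fn == 16

    def test_lr_plus_absent_when_fp_zero(self, mini_grouping):
        m = self._metrics(mini_grouping, tp=5, fp=0, tn=10, fn=0)
        assert m.lr_plus is None and m.lr_minus is None

    def test_category_absent_everywhere(self, mini_grouping):
        # tuberculosis never predicted nor gold: Sen undefined, Spe 100%
        pred = [_cls("T1", "mental")]
        gold = [_gold("T1", "mental")]
        out = per_category_metrics(pred, gold, mini_grouping)
        m = next(x for x in out if x.category_id == "tuberculosis")
        assert m.sensitivity is None
        assert m.specificity == 1.0

    def test_no_gbd_pseudo_category_scored(self, mini_grouping):
        pred = [_cls("T1"), _cls("T2", "mental")]
        gold = [_gold("T1"), _gold("T2")]
        out = per_category_metrics(pred, gold, mini_grouping)
        m = next(x for x in out if x.category_id == NO_GBD)
        assert (m.tp, m.fn) == (1, 1)

    def test_residual_categories_not_scored(self, mini_grouping):
        out = per_category_metrics([_cls("T1")], [_gold("T1")], mini_grouping)
        assert "other" not in {m.category_id for m in out}

    @given(st.integers(0, 400))
    def test_random_pairs_self_consistent(self, seed):
        """tp+fn equals gold positives; LR+ = Sen/(1-Spe) to 1e-10 relative."""
        from gbdmap.taxonomy import GBDCategory, GBDGrouping, parse_icd10

        grouping = GBDGrouping(
            "g",
            [GBDCategory("a", "A"), GBDCategory("b", "B")],
            {"a": [parse_icd10("A00-A09.9")], "b": [parse_icd10("B00-B09.9")]},
        )
        rng = np.random.default_rng(seed)
        cats = ["a", "b"]
        n = 30
        pred = [
            _cls(f"T{i}", *[c for c in cats if rng.random() < 0.3]) for i in range(n)
        ]
        gold = [
            _gold(f"T{i}", *[c for c in cats if rng.random() < 0.3]) for i in range(n)
        ]
        gold_counts = {c: sum(c in g.categories for g in gold) for c in cats}
        gold_counts[NO_GBD] = sum(not g.categories for g in gold)
        for m in per_category_metrics(pred, gold, grouping):
            assert m.tp + m.fn == gold_counts[m.category_id]
            assert m.tp + m.fp + m.tn + m.fn == n
            if m.lr_plus is not None:
                recomputed = m.sensitivity / (1 - m.specificity)
                assert math.isclose(m.lr_plus, recomputed, rel_tol=1e-10)
            if m.lr_minus is not None:
                recomputed = (1 - m.sensitivity) / m.specificity
                assert math.isclose(m.lr_minus, recomputed, rel_tol=1e-10)
        # exact matching of a prediction against itself is always 100%
        self_gold = [_gold(p.trial_id, *p.categories) for p in pred]
        assert exact_matching(pred, self_gold).overall.proportion == 1.0


class TestWeightedAverages:
    def _metric(self, cid, sen, spe):
        from gbdmap.evaluation import CategoryMetrics

        return CategoryMetrics(cid, 0, 0, 0, 0, sen, None, spe, None, None, None,
                               None, None, None, None)

    def test_equal_weights(self):
        metrics = [self._metric("a", 1.0, 0.9), self._metric("b", 0.5, 0.7)]
        gold = [_gold(f"T{i}", "a") for i in range(10)] + [
            _gold(f"U{i}", "b") for i in range(10)
        ]
        wsen, wspe = weighted_averages(metrics, gold)
        assert wsen == pytest.approx(0.75)
        assert wspe == pytest.approx(0.8)

    def test_unequal_weights(self):
        metrics = [self._metric("a", 0.9, 1.0), self._metric("b", 0.5, 1.0)]
        gold = [_gold(f"T{i}", "a") for i in range(30)] + [
            _gold(f"U{i}", "b") for i in range(10)
        ]
        wsen, _ = weighted_averages(metrics, gold)
        assert wsen == pytest.approx(0.8)

    def test_single_category_identity(self):
        metrics = [self._metric("a", 0.6, 0.9)]
        gold = [_gold("T1", "a")]
        assert weighted_averages(metrics, gold)[0] == pytest.approx(0.6)

    def test_no_gbd_included(self):
        metrics = [self._metric("a", 1.0, 1.0), self._metric(NO_GBD, 0.5, 1.0)]
        gold = [_gold("T1", "a"), _gold("T2")]
        assert weighted_averages(metrics, gold)[0] == pytest.approx(0.75)

    def test_order_invariant(self):
        metrics = [self._metric("a", 1.0, 0.9), self._metric("b", 0.5, 0.7)]
        gold = [_gold("T1", "a"), _gold("T2", "b"), _gold("T3", "b")]
        assert weighted_averages(metrics, gold) == weighted_averages(metrics[::-1], gold)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(EvaluationError):
            weighted_averages([self._metric("a", 1.0, 1.0)], [])


class TestProportionCI:
    def test_wilson_midpoint_example(self):
        lo, hi = proportion_ci(50, 100)
        assert lo == pytest.approx(0.404, abs=5e-4)
        assert hi == pytest.approx(0.596, abs=5e-4)

    def test_boundaries(self):
        assert proportion_ci(0, 10)[0] == 0.0
        assert proportion_ci(10, 10)[1] == 1.0

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)

    @given(st.integers(1, 200), st.data())
    def test_matches_reference_implementation(self, n, data):
        """Cross-check against statsmodels' Wilson interval."""
        from statsmodels.stats.proportion import proportion_confint

        k = data.draw(st.integers(0, n))
        lo, hi = proportion_ci(k, n)
        ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert lo == pytest.approx(ref_lo, abs=1e-9)
        assert hi == pytest.approx(ref_hi, abs=1e-9)


class TestEvaluateAndGoldIO:
    def test_full_report(self, mini_grouping):
        pred = [_cls("T1", "mental"), _cls("T2"), _cls("T3", "musculoskeletal")]
        gold = [_gold("T1", "mental"), _gold("T2"), _gold("T3", "mental")]
        report = evaluate(pred, gold, mini_grouping, sources={"T1": "s1", "T2": "s1", "T3": "s2"})
        assert report.exact.overall.hits == 2
        assert report.by_source["s1"].overall.proportion == 1.0
        assert report.by_source["s2"].overall.proportion == 0.0
        assert report.weighted_sensitivity is not None

    def test_gold_roundtrip(self, tmp_path):
        gold = [_gold("T1", "a", "b"), _gold("T2")]
        p = tmp_path / "gold.tsv"
        save_gold(gold, p)
        assert load_gold(p) == gold
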