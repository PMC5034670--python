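"""Diagnostic-accuracy evaluation against a gold standard.

Automatic classifications are compared to manual (gold) category sets
two ways:

* **Exact matching** — the proportion of trials whose predicted set
  equals the gold set exactly, overall and stratified by gold
  complexity (one category / two or more / none).
* **Per-category one-vs-rest metrics** — each category (plus the
  "No GBD" pseudo-category, scored positive when the set is empty) gets
  a 2x2 table over trials and from it sensitivity, specificity,
  positive predictive value and the likelihood ratios
  LR+ = Sen/(1-Spe), LR- = (1-Sen)/Spe.  LR+ > 10 rules a category in,
  LR- < 0.1 rules it out.

Proportions carry two-sided 95% Wilson score intervals; likelihood
ratios carry log-scale normal-approximation intervals.  Metrics with a
zero denominator are reported as absent (``None``), never as 0 or 100.
Weighted averages across categories weight each category (including
"No GBD") by its gold-positive trial count.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from scipy.stats import norm

from .classifier import Classification
from .taxonomy import GBDGrouping

#: pseudo-category scored positive when a trial's category set is empty
NO_GBD = "No GBD"

_Z = float(norm.ppf(0.975))


class EvaluationError(ValueError):
    """Predicted and gold trial ids do not line up, or weights degenerate."""


@dataclass(frozen=True)
class GoldLabel:
    """Manual gold-standard category set; empty means gold 'No GBD'."""

    trial_id: str
    categories: frozenset[str]


def proportion_ci(successes: int, n: int) -> tuple[float, float]:
    """Two-sided 95% Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("proportion_ci requires n > 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    p = successes / n
    z2 = _Z * _Z
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = _Z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == n else min(1.0, center + half)
    return (lo, hi)


def _lr_ci(lr: float, a: int, m: int, b: int, n: int) -> Optional[tuple[float, float]]:
    # log-method interval for a ratio of two proportions a/m and b/n
    if min(a, b) == 0 or lr <= 0:
        return None
    se = math.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (lr * math.exp(-_Z * se), lr * math.exp(_Z * se))


@dataclass(frozen=True)
class CategoryMetrics:
    """One-vs-rest counts and accuracy metrics for one category.

    All proportions are on the [0, 1] scale; absent (undefined) metrics
    are ``None``.
    """

    category_id: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    ppv: Optional[float]
    ppv_ci: Optional[tuple[float, float]]
    lr_plus: Optional[float]
    lr_plus_ci: Optional[tuple[float, float]]
    lr_minus: Optional[float]
    lr_minus_ci: Optional[tuple[float, float]]

    @property
    def gold_positives(self) -> int:
        return self.tp + self.fn


def _metrics_from_counts(category_id: str, tp: int, fp: int, tn: int, fn: int) -> CategoryMetrics:
    pos, neg, pred_pos = tp + fn, fp + tn, tp + fp
    sen = tp / pos if pos else None
    spe = tn / neg if neg else None
    ppv = tp / pred_pos if pred_pos else None
    # LR+ needs tp and fp non-zero (Sen > 0 and Spe < 1), LR- needs fn and tn
    lr_plus = lr_plus_ci = lr_minus = lr_minus_ci = None
    if pos and neg and tp > 0 and fp > 0:
        lr_plus = (tp / pos) / (fp / neg)
        lr_plus_ci = _lr_ci(lr_plus, tp, pos, fp, neg)
    if pos and neg and fn > 0 and tn > 0:
        lr_minus = (fn / pos) / (tn / neg)
        lr_minus_ci = _lr_ci(lr_minus, fn, pos, tn, neg)
    return CategoryMetrics(
        category_id,
        tp,
        fp,
        tn,
        fn,
        sen,
        proportion_ci(tp, pos) if pos else None,
        spe,
        proportion_ci(tn, neg) if neg else None,
        ppv,
        proportion_ci(tp, pred_pos) if pred_pos else None,
        lr_plus,
        lr_plus_ci,
        lr_minus,
        lr_minus_ci,
    )


@dataclass(frozen=True)
class StratumResult:
    hits: int
    n: int

    @property
    def proportion(self) -> Optional[float]:
        return self.hits / self.n if self.n else None


@dataclass(frozen=True)
class ExactMatchingResult:
    """Exact-matching hits overall and per gold stratum."""

    overall: StratumResult
    one_category: StratumResult
    two_or_more: StratumResult
    no_category: StratumResult


@dataclass(frozen=True)
class EvalReport:
    exact: ExactMatchingResult
    per_category: tuple[CategoryMetrics, ...]
    weighted_sensitivity: Optional[float]
    weighted_specificity: Optional[float]
    by_source: Optional[dict[str, ExactMatchingResult]] = None


def _pair(
    pred: Sequence[Classification], gold: Sequence[GoldLabel]
) -> list[tuple[frozenset[str], frozenset[str]]]:
    pred_map = {p.trial_id: p.categories for p in pred}
    gold_map = {g.trial_id: g.categories for g in gold}
    missing = sorted(set(gold_map) ^ set(pred_map))
    if missing:
        raise EvaluationError(f"unmatched trial ids: {missing}")
    if len(pred_map) != len(pred) or len(gold_map) != len(gold):
        raise EvaluationError("duplicate trial ids")
    return [(pred_map[tid], gold_map[tid]) for tid in sorted(gold_map)]


def exact_matching(
    pred: Sequence[Classification], gold: Sequence[GoldLabel]
) -> ExactMatchingResult:
    """Per-trial hit iff predicted set == gold set; stratified by gold size."""
    pairs = _pair(pred, gold)
    counts = {"one": [0, 0], "multi": [0, 0], "none": [0, 0]}
    for p_cats, g_cats in pairs:
        stratum = "none" if not g_cats else ("one" if len(g_cats) == 1 else "multi")
        counts[stratum][1] += 1
        if p_cats == g_cats:
            counts[stratum][0] += 1
    total_hits = sum(c[0] for c in counts.values())
    return ExactMatchingResult(
        overall=StratumResult(total_hits, len(pairs)),
        one_category=StratumResult(*counts["one"]),
        two_or_more=StratumResult(*counts["multi"]),
        no_category=StratumResult(*counts["none"]),
    )


def per_category_metrics(
    pred: Sequence[Classification],
    gold: Sequence[GoldLabel],
    grouping: GBDGrouping,
) -> list[CategoryMetrics]:
    """One-vs-rest metrics for every non-residual category plus "No GBD"."""
    pairs = _pair(pred, gold)
    out = []
    for cid in [c.id for c in grouping.non_residual] + [NO_GBD]:
        tp = fp = tn = fn = 0
        for p_cats, g_cats in pairs:
            if cid == NO_GBD:
                predicted, actual = not p_cats, not g_cats
            else:
                predicted, actual = cid in p_cats, cid in g_cats
            if predicted and actual:
                tp += 1
            elif predicted:
                fp += 1
            elif actual:
                fn += 1
            else:
                tn += 1
        out.append(_metrics_from_counts(cid, tp, fp, tn, fn))
    return out


def weighted_averages(
    metrics: Iterable[CategoryMetrics], gold: Sequence[GoldLabel]
) -> tuple[Optional[float], Optional[float]]:
    """Average Sen and Spe across categories, weighted by gold-positive counts.

    Categories with an undefined metric (or zero weight) drop out of
    that metric's average; all-zero weights raise.
    """
    weights: dict[str, int] = {}
    for g in gold:
        if g.categories:
            for cid in g.categories:
                weights[cid] = weights.get(cid, 0) + 1
        else:
            weights[NO_GBD] = weights.get(NO_GBD, 0) + 1
    if not weights or sum(weights.values()) == 0:
        raise EvaluationError("weighted averages require at least one gold-positive trial")

    def _avg(pick) -> Optional[float]:
        num = den = 0.0
        for m in metrics:
            w = weights.get(m.category_id, 0)
            v = pick(m)
            if w > 0 and v is not None:
                num += w * v
                den += w
        return num / den if den else None

    metrics = list(metrics)
    return _avg(lambda m: m.sensitivity), _avg(lambda m: m.specificity)


def evaluate(
    pred: Sequence[Classification],
    gold: Sequence[GoldLabel],
    grouping: GBDGrouping,
    sources: Optional[dict[str, str]] = None,
) -> EvalReport:
    """Full evaluation: exact matching, per-category metrics, weighted averages.

    ``sources`` optionally maps trial ids to data-source labels for a
    per-source exact-matching breakdown.
    """
    exact = exact_matching(pred, gold)
    metrics = per_category_metrics(pred, gold, grouping)
    wsen, wspe = weighted_averages(metrics, gold)
    by_source = None
    if sources is not None:
        by_source = {}
        for label in sorted(set(sources.values())):
            ids = {tid for tid, s in sources.items() if s == label}
            sub_pred = [p for p in pred if p.trial_id in ids]
            sub_gold = [g for g in gold if g.trial_id in ids]
            by_source[label] = exact_matching(sub_pred, sub_gold)
    return EvalReport(exact, tuple(metrics), wsen, wspe, by_source)


# --- gold label IO -----------------------------------------------------------


def load_gold(path: Union[str, Path]) -> list[GoldLabel]:
    """Read gold labels from TSV (trial_id, categories semicolon-joined)."""
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or not {"trial_id", "categories"} <= set(reader.fieldnames):
            raise EvaluationError(f"{path}: expected columns trial_id, categories")
        for row in reader:
            cats = frozenset(c.strip() for c in (row["categories"] or "").split(";") if c.strip())
            out.append(GoldLabel(row["trial_id"].strip(), cats))
    return out


def save_gold(labels: Iterable[GoldLabel], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("trial_id", "categories"))
        for g in labels:
            writer.writerow((g.trial_id, ";".join(sorted(g.categories))))
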