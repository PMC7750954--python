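"""Precision/recall/F-beta benchmarking of predicted annotations.

The benchmark protocol compares engine predictions on records that were
subsequently expert-reviewed against the reviewed (gold) annotation sets,
counting over (accession, annotation) pairs:

    P = TP / (TP + FP)        R = TP / (TP + FN)

    F_beta = (beta^2 + 1) * P * R / (beta^2 * P + R)

with beta = R/P controlling the precision/recall balance (beta = 1 is the
harmonic mean F1; beta < 1 is precision-oriented).  For a production rule
system precision is constrained to [0.95, 1] while recall may be anything in
]0, 1], so the operating-point beta — here called *unp-beta* — is estimated
from the interval midpoints: 0.5 / 0.975 = 0.51 (2 dp).

Note the literature sometimes prints this estimate with numerator and
denominator transposed; this module follows the definition beta = R/P,
which is the reading consistent with the 0.51 value itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .engine import AnnotationResult
from .quality_stats import annotation_key
from .rule_model import Annotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkResult:
    """Counts and quality measures for one benchmark (or one period of one)."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    f_beta: float
    beta: float
    period: str | None = None


def match_predictions(
    predicted: Iterable[AnnotationResult | tuple[str, Annotation]],
    gold: Iterable[tuple[str, Annotation]],
) -> tuple[int, int, int]:
    """Count TP/FP/FN over (accession, annotation) pairs.

    Pairs are compared with the same annotation comparator as the curator
    statistics (category/subtype, normalised free-text value).  ``predicted``
    accepts either engine results or bare (accession, annotation) pairs.
    """
    def as_pair(item):
        if isinstance(item, AnnotationResult):
            return (item.accession, annotation_key(item.annotation))
        acc, ann = item
        return (acc, annotation_key(ann))

    pred_set = {as_pair(p) for p in predicted}
    gold_set = {(acc, annotation_key(ann)) for acc, ann in gold}
    tp = len(pred_set & gold_set)
    fp = len(pred_set - gold_set)
    fn = len(gold_set - pred_set)
    return tp, fp, fn


def f_beta(precision: float, recall: float, beta: float) -> float:
    """The weighted harmonic mean (beta^2+1)PR / (beta^2 P + R).

    Undefined when P = R = 0 (raises); equals P = R at any beta when they
    coincide; reduces to F1 at beta = 1.
    """
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if precision == 0 and recall == 0:
        raise ValueError("F-beta undefined for P = R = 0")
    denominator = beta**2 * precision + recall
    if denominator == 0:
        return 0.0
    return (beta**2 + 1) * precision * recall / denominator


def unp_beta(
    precision_interval: tuple[float, float] = (0.95, 1.0),
    recall_interval: tuple[float, float] = (0.0, 1.0),
    decimals: int = 2,
) -> float:
    """The precision-oriented operating-point beta.

    beta = R/P estimated as the ratio of the admissible-interval midpoints:
    average recall over ]0, 1] divided by average precision over [0.95, 1],
    rounded to ``decimals`` places.  Defaults give 0.51.
    """
    mid_r = (recall_interval[0] + recall_interval[1]) / 2
    mid_p = (precision_interval[0] + precision_interval[1]) / 2
    return round(mid_r / mid_p, decimals)


def evaluate(
    predicted,
    gold,
    beta: float | None = None,
    period: str | None = None,
) -> BenchmarkResult:
    """Run the full benchmark on one prediction/gold pair of annotation sets."""
    if beta is None:
        beta = unp_beta()
    tp, fp, fn = match_predictions(predicted, gold)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision == 0 and recall == 0:
        f1 = fb = 0.0
    else:
        f1 = f_beta(precision, recall, 1.0)
        fb = f_beta(precision, recall, beta)
    return BenchmarkResult(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall,
        f1=f1, f_beta=fb, beta=beta, period=period,
    )


def benchmark_series(
    predictions_by_period: Mapping[str, Iterable],
    gold_by_period: Mapping[str, Iterable[tuple[str, Annotation]]],
    beta: float | None = None,
) -> list[BenchmarkResult]:
    """Per-period benchmark (e.g. one result per year of a release series).

    Periods with no gold records are omitted with a warning; the remaining
    periods are reported in the order they appear in ``gold_by_period``.
    """
    out: list[BenchmarkResult] = []
    for period, gold in gold_by_period.items():
        gold = list(gold)
        if not gold:
            logger.warning("period %s has no gold records; omitted", period)
            continue
        predicted = list(predictions_by_period.get(period, []))
        out.append(evaluate(predicted, gold, beta=beta, period=period))
    return out
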