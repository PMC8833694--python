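"""Diagnostic-performance evaluation against histopathology ground truth.

The evaluation unit is the tumor-draining (left) node of each subject;
its pathology label is the gold standard.  For every binary imaging
parameter, and for every sum-score positivity threshold, a 2x2 confusion
matrix yields sensitivity, specificity, PPV, NPV and diagnostic accuracy,
each with an exact (Clopper-Pearson) two-sided 95% confidence interval.
Nodes whose prediction is unavailable (e.g. CEUS unusable) are excluded
from that parameter's matrix only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyEvaluationError, InvalidInputError
from .scoring import PARAMETER_NAMES, ScoreCard, round_half_away

__all__ = [
    "DiagnosticResult",
    "confusion",
    "clopper_pearson",
    "evaluate_parameter",
    "evaluate_sum_threshold",
    "threshold_sweep",
    "report_table",
    "SUM_THRESHOLDS",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
SUM_THRESHOLDS = (0, 20, 40, 60, 80, 100)


@dataclass
class DiagnosticResult:
    """Confusion counts and the five performance metrics with exact CIs.

    ``metrics`` maps metric name to (point, lower, upper) proportions, or
    to None when the metric's denominator is zero (undefined, never 0).
    """

    label: str
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict[str, tuple[float, float, float] | None]

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def formatted(self, metric: str) -> str:
        """Render one metric as 'point [lower-upper]' in rounded percent."""
        m = self.metrics[metric]
        if m is None:
            return "undefined"
        point, lo, hi = m
        return (
            f"{round_half_away(100 * point)} "
            f"[{round_half_away(100 * lo)}-{round_half_away(100 * hi)}]"
        )


def confusion(
    predictions: np.ndarray, truths: np.ndarray
) -> tuple[int, int, int, int]:
    """Standard 2x2 counts (tp, fp, tn, fn) from boolean arrays."""
    predictions = np.asarray(predictions, dtype=bool)
    truths = np.asarray(truths, dtype=bool)
    if predictions.shape != truths.shape:
        raise InvalidInputError("predictions and truths must align")
    if predictions.size == 0:
        raise EmptyEvaluationError("no evaluable nodes")
    tp = int(np.sum(predictions & truths))
    fp = int(np.sum(predictions & ~truths))
    tn = int(np.sum(~predictions & ~truths))
    fn = int(np.sum(~predictions & truths))
    return tp, fp, tn, fn


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta-quantile form)."""
    if trials < 1 or not (0 <= successes <= trials):
        raise InvalidInputError(f"invalid counts {successes}/{trials}")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes)
    )
    return lo, hi


def _result_from_counts(
    label: str, tp: int, fp: int, tn: int, fn: int, confidence: float
) -> DiagnosticResult:
    n = tp + fp + tn + fn
    fractions = {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
        "accuracy": (tp + tn, n),
    }
    metrics: dict[str, tuple[float, float, float] | None] = {}
    for name, (k, d) in fractions.items():
        if d == 0:
            metrics[name] = None
        else:
            lo, hi = clopper_pearson(k, d, confidence)
            metrics[name] = (k / d, lo, hi)
    return DiagnosticResult(label=label, tp=tp, fp=fp, tn=tn, fn=fn, metrics=metrics)


def _pathology_lookup(
    scorecards: list[ScoreCard], pathology: dict[str, bool]
) -> list[bool]:
    missing = [c.subject_id for c in scorecards if c.subject_id not in pathology]
    if missing:
        raise InvalidInputError(f"no pathology label for subjects {missing}")
    return [bool(pathology[c.subject_id]) for c in scorecards]


def evaluate_parameter(
    scorecards: list[ScoreCard],
    pathology: dict[str, bool],
    parameter_name: str,
    confidence: float = 0.95,
) -> DiagnosticResult:
    """Diagnostic performance of one binary parameter vs pathology.

    Subjects whose parameter is unavailable are dropped from this
    evaluation (the matrix shrinks; it is never imputed).
    """
    if parameter_name not in PARAMETER_NAMES:
        raise InvalidInputError(f"unknown parameter {parameter_name!r}")
    truths_all = _pathology_lookup(scorecards, pathology)
    preds, truths = [], []
    for card, truth in zip(scorecards, truths_all):
        s = card.scores[parameter_name]
        if s is None:
            continue
        preds.append(bool(s))
        truths.append(truth)
    tp, fp, tn, fn = confusion(np.array(preds), np.array(truths))
    return _result_from_counts(parameter_name, tp, fp, tn, fn, confidence)


def evaluate_sum_threshold(
    scorecards: list[ScoreCard],
    pathology: dict[str, bool],
    threshold_percent: float,
    confidence: float = 0.95,
) -> DiagnosticResult:
    """Diagnostic performance of the sum score at one positivity threshold.

    A node is predicted positive iff its sum percent reaches the threshold
    AND is strictly positive — at threshold 0 an all-zero scorecard still
    counts as negative (otherwise every node would be positive and the
    threshold-0 operating point would be vacuous).
    """
    truths = _pathology_lookup(scorecards, pathology)
    preds = [
        (c.sum_percent >= threshold_percent) and (c.sum_percent > 0)
        for c in scorecards
    ]
    tp, fp, tn, fn = confusion(np.array(preds), np.array(truths))
    return _result_from_counts(
        f"sum>={threshold_percent:g}", tp, fp, tn, fn, confidence
    )


def threshold_sweep(
    scorecards: list[ScoreCard],
    pathology: dict[str, bool],
    thresholds: tuple[int, ...] = SUM_THRESHOLDS,
    confidence: float = 0.95,
) -> dict[int, DiagnosticResult]:
    """Sum-score evaluation at every positivity threshold."""
    return {
        t: evaluate_sum_threshold(scorecards, pathology, t, confidence)
        for t in thresholds
    }


def report_table(
    scorecards: list[ScoreCard],
    pathology: dict[str, bool],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Performance report: individual parameters, then the threshold sweep.

    Cells are 'point [lower-upper]' strings in rounded percent; rounding
    is applied at report time only, all comparisons upstream use exact
    fractions.
    """
    if not scorecards:
        raise EmptyEvaluationError("no scorecards to evaluate")
    rows = []
    for name in PARAMETER_NAMES:
        res = evaluate_parameter(scorecards, pathology, name, confidence)
        rows.append((name, res))
    for t, res in threshold_sweep(scorecards, pathology, confidence=confidence).items():
        rows.append((f"sum score {t}", res))
    return pd.DataFrame(
        {
            "variable": [label for label, _ in rows],
            "n": [res.n_evaluated for _, res in rows],
            **{
                metric: [res.formatted(metric) for _, res in rows]
                for metric in METRIC_NAMES
            },
        }
    )
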