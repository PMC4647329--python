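"""ROC analysis over scale totals and the validation confusion matrix.

The decision rule is fixed throughout: a total score strictly greater than
the cutoff predicts *poor* recovery.  The confusion counts follow the
clinical convention of the source instrument — TG (true good), FP (false
poor: actually good, predicted poor), TP (true poor), FG (false good) — and
the derived metrics are

* sensitivity = TG / (TG + FP)  — the detection rate of GOOD recovery,
* specificity = TP / (TP + FG)  — the detection rate of poor recovery,
* accuracy    = (TG + TP) / (TG + FG + TP + FP).

The ROC sweeps candidate cutoffs over the observed score values (plus one
sentinel below the minimum, under which every patient is predicted poor) and
the operating cutoff is the one maximizing Youden's index
(sensitivity + specificity - 1), ties broken toward the smallest cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Outcome
from .errors import EvaluationError

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "confusion",
    "metrics",
    "roc_curve",
    "youden_cutoff",
    "auc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TG/FP/TP/FG counts under the score > cutoff => poor rule."""

    tg: int  # actual good, predicted good
    fp: int  # actual good, predicted poor
    tp: int  # actual poor, predicted poor
    fg: int  # actual poor, predicted good

    def __post_init__(self) -> None:
        if min(self.tg, self.fp, self.tp, self.fg) < 0:
            raise EvaluationError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tg + self.fp + self.tp + self.fg

    @property
    def n_correct(self) -> int:
        return self.tg + self.tp


@dataclass(frozen=True)
class RocCurve:
    """Per-cutoff sensitivity/specificity sweep with Youden's index."""

    cutoffs: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    youden: np.ndarray


def _to_poor_indicator(outcomes) -> np.ndarray:
    return np.asarray(
        [1 if (o is Outcome.POOR or o == "poor" or o == 1) else 0 for o in outcomes],
        dtype=bool,
    )


def confusion(scores: Sequence[float], outcomes, cutoff: float) -> ConfusionMatrix:
    """Tally the confusion counts at one cutoff (strict > rule)."""
    s = np.asarray(scores, dtype=float)
    poor = _to_poor_indicator(outcomes)
    if s.size == 0 or s.shape != poor.shape:
        raise EvaluationError("scores and outcomes must be equal-length and nonempty")
    pred_poor = s > cutoff
    return ConfusionMatrix(
        tg=int(np.sum(~poor & ~pred_poor)),
        fp=int(np.sum(~poor & pred_poor)),
        tp=int(np.sum(poor & pred_poor)),
        fg=int(np.sum(poor & ~pred_poor)),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) with sensitivity = good detection."""
    if cm.tg + cm.fp == 0:
        raise EvaluationError("sensitivity undefined: no actual-good patients (TG + FP = 0)")
    if cm.tp + cm.fg == 0:
        raise EvaluationError("specificity undefined: no actual-poor patients (TP + FG = 0)")
    sens = cm.tg / (cm.tg + cm.fp)
    spec = cm.tp / (cm.tp + cm.fg)
    acc = (cm.tg + cm.tp) / cm.n
    return sens, spec, acc


def roc_curve(scores: Sequence[float], outcomes) -> RocCurve:
    """Sweep candidate cutoffs over observed scores plus a low sentinel.

    Raises on single-class input (sensitivity or specificity would be
    undefined at every cutoff).
    """
    s = np.asarray(scores, dtype=float)
    poor = _to_poor_indicator(outcomes)
    if s.size == 0 or s.shape != poor.shape:
        raise EvaluationError("scores and outcomes must be equal-length and nonempty")
    if poor.all() or not poor.any():
        raise EvaluationError("ROC needs both outcome classes present")
    distinct = np.unique(s)
    cutoffs = np.concatenate(([distinct[0] - 1.0], distinct))
    sens = np.empty_like(cutoffs)
    spec = np.empty_like(cutoffs)
    for i, c in enumerate(cutoffs):
        se, sp, _ = metrics(confusion(s, poor, c))
        sens[i] = se
        spec[i] = sp
    return RocCurve(cutoffs=cutoffs, sens=sens, spec=spec, youden=sens + spec - 1.0)


def youden_cutoff(curve: RocCurve) -> float:
    """Cutoff maximizing Youden's index; ties break to the smallest cutoff."""
    if curve.cutoffs.size == 0:
        raise EvaluationError("empty ROC curve")
    best = int(np.argmax(curve.youden))  # argmax returns the first (smallest) maximizer
    return float(curve.cutoffs[best])


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the poor-detection ROC (convenience statistic)."""
    # specificity here detects poor; 1 - sens is the false-poor... build the
    # standard (FPR, TPR) pairs for "poor" as the positive class.
    tpr = curve.spec            # poor detection rate
    fpr = 1.0 - curve.sens      # good patients predicted poor
    order = np.lexsort((tpr, fpr))  # staircase: ascending FPR, then TPR
    return float(np.trapezoid(tpr[order], fpr[order]))
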