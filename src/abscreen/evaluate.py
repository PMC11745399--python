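"""Comparison of machine decisions against first-reviewer labels.

Covers the standard dual-reviewer accounting for machine-assisted
screening: a 2x2 confusion matrix (positive = included at screening 1),
classification metrics (precision, recall, specificity, F1, MCC),
chance-corrected agreement (Cohen's kappa and PABAK = 2*p0 - 1, which
fixes expected chance agreement at 0.5 and is therefore robust to the
heavy class imbalance typical of screening corpora), workload-reduction
accounting against the *original* number of identified records, and
per-criterion point-biserial (Pearson on 0/1) correlations with the human
decision.

Metrics with a zero denominator are reported as ``None`` — an explicit
undefined flag — never coerced to 0, so aggregation can't silently
average them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .decide import CriteriaMatrix, DecisionVector
from .errors import AccountingError, AlignmentError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "AgreementStats",
    "WorkloadReport",
    "confusion",
    "classification_metrics",
    "agreement_stats",
    "workload_reduction",
    "criterion_correlations",
    "evaluate_decisions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; positive = included at screening 1."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n < 1:
            raise ValueError("confusion matrix must count at least one pair")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    mcc: float | None


@dataclass(frozen=True)
class AgreementStats:
    p0: float
    kappa: float | None
    pabak: float


@dataclass(frozen=True)
class WorkloadReport:
    """Second-reviewer workload accounting.

    ``correct`` records (machine and first reviewer agree) need no second
    look; everything else — disagreements, records the pipeline failed to
    process, and records dropped in preprocessing — remains on the second
    reviewer's desk, which is why the denominator is the *original*
    record count.
    """

    correct: int
    original_total: int
    remaining: int
    reduction_percent: int


def _align(decisions: DecisionVector, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(decisions.decision, dtype=bool)
    if isinstance(truth, Mapping):
        missing = [i for i in decisions.record_ids if i not in truth]
        if missing:
            raise AlignmentError(f"truth labels missing for ids: {missing[:5]}")
        y = np.array([truth[i] for i in decisions.record_ids], dtype=bool)
    else:
        y = np.asarray(truth, dtype=bool)
        if len(y) != len(pred):
            raise AlignmentError(
                f"{len(pred)} decisions vs {len(y)} truth labels"
            )
    return pred, y


def confusion(decisions: DecisionVector, truth) -> ConfusionMatrix:
    """Tally agreement/disagreement pairs between decisions and truth.

    ``truth`` is either a Boolean sequence aligned with the decision
    vector or a mapping record_id -> bool.
    """
    pred, y = _align(decisions, truth)
    return ConfusionMatrix(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, specificity, F1 and MCC from the four cells."""
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    mcc = (
        None
        if denom == 0
        else (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    )
    return MetricsReport(
        precision=precision, recall=recall, specificity=specificity, f1=f1, mcc=mcc
    )


def agreement_stats(cm: ConfusionMatrix) -> AgreementStats:
    """Observed agreement, Cohen's kappa and PABAK.

    p0 = (tp+tn)/n. Kappa corrects p0 by the marginal-product chance
    agreement pe and is undefined (None) when pe = 1. PABAK replaces pe
    with the constant 0.5, giving exactly 2*p0 - 1.
    """
    n = cm.n
    p0 = (cm.tp + cm.tn) / n
    p_yes_a = (cm.tp + cm.fp) / n  # machine includes
    p_yes_b = (cm.tp + cm.fn) / n  # human includes
    pe = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    kappa = None if pe == 1.0 else (p0 - pe) / (1 - pe)
    return AgreementStats(p0=p0, kappa=kappa, pabak=2 * p0 - 1)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def workload_reduction(correct: int, original_total: int) -> WorkloadReport:
    """Workload left for a second reviewer, against the original total.

    ``reduction_percent`` is 100 * correct / original_total rounded
    half-away-from-zero to an integer percent.
    """
    if original_total < 1:
        raise AccountingError("original_total must be >= 1")
    if not (0 <= correct <= original_total):
        raise AccountingError(
            f"correct ({correct}) must be between 0 and original_total "
            f"({original_total})"
        )
    return WorkloadReport(
        correct=correct,
        original_total=original_total,
        remaining=original_total - correct,
        reduction_percent=_round_half_away(100.0 * correct / original_total),
    )


def criterion_correlations(
    matrix: CriteriaMatrix, truth: Sequence[bool] | np.ndarray | Mapping[str, bool]
) -> dict[str, float | None]:
    """Pearson r between each 0/1 criterion column and the 0/1 human label.

    With Boolean coding this is the point-biserial correlation. Constant
    columns (or a constant label) are flagged None. Output is ordered by
    criterion key for stable heatmap rendering.
    """
    if isinstance(truth, Mapping):
        y = np.array([truth[i] for i in matrix.record_ids], dtype=float)
    else:
        y = np.asarray(truth, dtype=float)
        if len(y) != len(matrix.record_ids):
            raise AlignmentError("truth labels do not align with matrix rows")
    out: dict[str, float | None] = {}
    y_const = np.ptp(y) == 0
    order = sorted(range(len(matrix.criterion_keys)), key=lambda j: matrix.criterion_keys[j])
    for j in order:
        col = matrix.values[:, j].astype(float)
        if y_const or np.ptp(col) == 0:
            out[matrix.criterion_keys[j]] = None
        else:
            out[matrix.criterion_keys[j]] = float(np.corrcoef(col, y)[0, 1])
    return out


def evaluate_decisions(
    decisions: DecisionVector,
    truth,
    original_total: int | None = None,
    status: Sequence[str] | None = None,
) -> dict:
    """One-stop evaluation: confusion, metrics, agreement and workload.

    ``original_total`` defaults to the number of compared records; pass
    the pre-preprocessing count to account for dropped records as
    remaining workload. When per-record ``status`` is given (aligned
    "ok"/"failed" strings), comparison is restricted to successfully
    processed records: a failed record never counts as agreement — even
    though its defaulted all-false decision may coincide with the human
    label — so it always stays in the remaining workload.
    """
    if status is not None:
        if len(status) != len(decisions.record_ids):
            raise AlignmentError("status does not align with decisions")
        keep = np.array([s == "ok" for s in status], dtype=bool)
        if isinstance(truth, Mapping):
            truth = [truth[i] for i in decisions.record_ids]
        truth = np.asarray(list(truth), dtype=bool)[keep]
        decisions = DecisionVector(
            record_ids=[i for i, k in zip(decisions.record_ids, keep) if k],
            decision=np.asarray(decisions.decision, dtype=bool)[keep],
            rule=decisions.rule,
        )
    cm = confusion(decisions, truth)
    metrics = classification_metrics(cm)
    agreement = agreement_stats(cm)
    workload = workload_reduction(cm.correct, original_total or cm.n)
    return {
        "confusion": cm,
        "metrics": metrics,
        "agreement": agreement,
        "workload": workload,
    }
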