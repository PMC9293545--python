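"""Confusion counts, derived screening metrics and cross-validated evaluation.

Accuracy is reported as a percentage (0-100); precision, recall, specificity
and F-score as fractions.  Metrics with a zero denominator are flagged with
the :data:`NOT_DEFINED` sentinel rather than silently coerced.

A legacy F-score variant circulating in some reports uses a true-negative
term in its denominator, contradicting the harmonic-mean definition; the
standard F1 (with false negatives) is the default and the legacy variant is
available behind ``f_score_variant="as_printed"`` for auditing only.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ValidationError
from .optimization import OptimizationParams, train_multiclass
from .tabular_data import Dataset


class _NotDefined:
    __slots__ = ()

    def __repr__(self) -> str:
        return "NOT_DEFINED"


#: Sentinel for metrics whose denominator is zero.
NOT_DEFINED = _NotDefined()

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f_score")


@dataclass(frozen=True)
class ConfusionCounts:
    tpos: int
    tneg: int
    fpos: int
    fneg: int

    def __post_init__(self) -> None:
        if min(self.tpos, self.tneg, self.fpos, self.fneg) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tpos + self.tneg + self.fpos + self.fneg


@dataclass(frozen=True)
class MetricsReport:
    accuracy: object  # percent in [0, 100] or NOT_DEFINED
    precision: object
    recall: object
    specificity: object
    f_score: object

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_counts(
    truth: Sequence[str], predicted: Sequence[str], positive_class: str
) -> ConfusionCounts:
    """Exact cross-tabulation of predictions against truth."""
    if len(truth) != len(predicted):
        raise ValidationError(
            f"length mismatch: {len(truth)} truth labels vs {len(predicted)} predictions"
        )
    if len(truth) == 0:
        raise ValidationError("need at least one (truth, prediction) pair")
    tp = tn = fp = fn = 0
    for t, y in zip(truth, predicted):
        t_pos = str(t) == str(positive_class)
        y_pos = str(y) == str(positive_class)
        if t_pos and y_pos:
            tp += 1
        elif t_pos:
            fn += 1
        elif y_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int):
    return num / den if den else NOT_DEFINED


def compute_metrics(c: ConfusionCounts, f_score_variant: str = "standard") -> MetricsReport:
    """Accuracy (%), precision, recall, specificity, F-score from counts.

    ``f_score_variant="as_printed"`` selects the non-standard legacy
    denominator (2*Tpos + Fpos + Tneg) for auditing.
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero instances")
    accuracy = 100.0 * (c.tpos + c.tneg) / c.total
    precision = _ratio(c.tpos, c.tpos + c.fpos)
    recall = _ratio(c.tpos, c.tpos + c.fneg)
    specificity = _ratio(c.tneg, c.tneg + c.fpos)
    if f_score_variant == "standard":
        f_score = _ratio(2 * c.tpos, 2 * c.tpos + c.fpos + c.fneg)
    elif f_score_variant == "as_printed":
        f_score = _ratio(2 * c.tpos, 2 * c.tpos + c.fpos + c.tneg)
    else:
        raise ValidationError(f"unknown f_score_variant {f_score_variant!r}")
    return MetricsReport(accuracy, precision, recall, specificity, f_score)


@dataclass
class CrossValidationResult:
    fold_counts: list[ConfusionCounts]
    fold_reports: list[MetricsReport]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @property
    def folds(self) -> int:
        return len(self.fold_reports)


def _aggregate(reports: list[MetricsReport]) -> tuple[dict, dict]:
    mean: dict = {}
    sd: dict = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not NOT_DEFINED]
        if not vals:
            mean[name] = NOT_DEFINED
            sd[name] = NOT_DEFINED
        else:
            mean[name] = statistics.fmean(vals)
            sd[name] = statistics.stdev(vals) if len(vals) > 1 else 0.0
    return mean, sd


def cross_validate(
    data: Dataset,
    folds: int,
    seed: int = 1,
    params: OptimizationParams | None = None,
    positive_class: str | None = None,
    stratified: bool = True,
    f_score_variant: str = "standard",
) -> CrossValidationResult:
    """K-fold cross-validation of the rule learner on ``data``.

    Fold assignment is deterministic in ``seed``; the model is retrained per
    fold.  ``positive_class`` defaults to the rarest class.
    """
    params = params or OptimizationParams()
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    labels = [inst.label for inst in data.instances]
    if any(l is None for l in labels):
        raise ValidationError("cross-validation requires fully labeled data")
    counts: dict[str, int] = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    if positive_class is None:
        positive_class = min(sorted(counts), key=lambda c: counts[c])
    if stratified:
        rarest = min(counts.values())
        if rarest < folds:
            raise ValidationError(
                f"a class has only {rarest} members (< {folds} folds); "
                "use stratified=False for unstratified folds"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(labels)), np.array(labels, dtype=object))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(labels)))

    fold_counts: list[ConfusionCounts] = []
    fold_reports: list[MetricsReport] = []
    for train_idx, test_idx in split_iter:
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        model = train_multiclass(train, params)
        predicted = model.predict_dataset(test)
        truth = [inst.label for inst in test.instances]
        c = confusion_counts(truth, predicted, positive_class)
        fold_counts.append(c)
        fold_reports.append(compute_metrics(c, f_score_variant))
    mean, sd = _aggregate(fold_reports)
    return CrossValidationResult(fold_counts, fold_reports, mean, sd)
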