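"""Classification metrics: precision / recall / F-score, ROC curves and the
performance-versus-domain-count breakdown.

F-score is F1, the unweighted harmonic mean of precision and recall.
Per-class metrics are always computed independently; any averaging over
classes is done explicitly by the caller and reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .architectures import DomainArchitecture, count_domains


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @staticmethod
    def from_sets(predicted: set, truth: set) -> "ConfusionCounts":
        return ConfusionCounts(
            tp=len(predicted & truth),
            fp=len(predicted - truth),
            fn=len(truth - predicted),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class PRF:
    """Precision, recall, F1.  A metric whose denominator is zero is
    reported as 0 and named in ``flagged``."""

    precision: float
    recall: float
    fscore: float
    flagged: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.precision, self.recall, self.fscore))


def prf(c: ConfusionCounts) -> PRF:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = harmonic mean."""
    flagged = []
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = 0.0
        flagged.append("precision")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = 0.0
        flagged.append("recall")
    if precision + recall > 0:
        fscore = 2 * precision * recall / (precision + recall)
    else:
        fscore = 0.0
    return PRF(precision, recall, fscore, tuple(flagged))


@dataclass(frozen=True)
class RocCurve:
    """ROC points from (0,0) to (1,1) with trapezoidal AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve and AUC from continuous scores and binary labels.

    Thresholds sweep the distinct score values; tied scores collapse into a
    single step.  Requires at least one positive and one negative label.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both a positive and a negative label")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(points=tuple(zip(fpr, tpr)), auc=float(_sk_auc(fpr, tpr)))


def by_domain_count(
    predictions: Mapping[str, set],
    truth: Mapping[str, set],
    das: Mapping[str, DomainArchitecture],
) -> pd.DataFrame:
    """Pooled metrics stratified by the number of real domains per protein.

    ``predictions`` and ``truth`` map protein ids to term sets; every
    protein in ``truth`` must have a DA.  Proteins missing from
    ``predictions`` contribute an empty prediction set (pure false
    negatives).  Returns one row per observed domain count.
    """
    pooled: dict[int, ConfusionCounts] = {}
    for pid, true_terms in truth.items():
        n = count_domains(das[pid])
        c = ConfusionCounts.from_sets(set(predictions.get(pid, set())), set(true_terms))
        pooled[n] = pooled.get(n, ConfusionCounts(0, 0, 0)) + c
    rows = []
    for n in sorted(pooled):
        c = pooled[n]
        m = prf(c)
        rows.append(
            dict(domain_count=n, tp=c.tp, fp=c.fp, fn=c.fn,
                 precision=m.precision, recall=m.recall, fscore=m.fscore)
        )
    return pd.DataFrame(
        rows,
        columns=["domain_count", "tp", "fp", "fn",
                 "precision", "recall", "fscore"],
    )
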