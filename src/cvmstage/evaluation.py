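"""Confusion-matrix construction and staging performance metrics.

Per-stage metrics are one-vs-rest: for stage s, TP are subjects of true
stage s predicted s, FP other subjects predicted s, FN stage-s subjects
predicted otherwise.  precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R).  Overall accuracy is the multiclass trace/N (the per-class
TN terms cancel in the 4-class view).  0/0 metrics are reported as NaN
("undefined"), never coerced to 0 or 1; macro averages skip undefined
entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

STAGES = (1, 2, 3, 4)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN if undefined."""
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0.0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = true stage, columns = predicted stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (4, 4):
            raise ValidationError(f"confusion matrix must be 4x4, got shape {c.shape}")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)) or (c < 0).any():
                raise ValidationError("confusion-matrix entries must be nonnegative integers")
            c = c.astype(np.int64)
        self.counts = c.astype(np.int64)

    @classmethod
    def from_labels(
        cls, true_stages: Sequence[int], predicted_stages: Sequence[int]
    ) -> "ConfusionMatrix":
        t = np.asarray(true_stages)
        p = np.asarray(predicted_stages)
        if t.shape != p.shape:
            raise ValidationError(
                f"label sequences differ in length: {t.shape[0]} vs {p.shape[0]}"
            )
        for name, arr in (("true", t), ("predicted", p)):
            bad = ~np.isin(arr, STAGES)
            if bad.any():
                raise ValidationError(
                    f"{name} stage label {arr[bad][0]!r} outside {STAGES}"
                )
        counts = np.zeros((4, 4), dtype=np.int64)
        if t.size:
            np.add.at(counts, (t.astype(int) - 1, p.astype(int) - 1), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"iCS{j}" for j in STAGES]
        return pd.DataFrame(self.counts, index=pd.Index(labels, name="true"),
                            columns=pd.Index(labels, name="predicted"))


@dataclass
class StageMetrics:
    stage: int
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    support: int


def per_stage_metrics(cm: ConfusionMatrix, stage: int) -> StageMetrics:
    """One-vs-rest precision/recall/F1 for one stage (NaN when 0/0)."""
    if stage not in STAGES:
        raise ValidationError(f"stage {stage!r} outside {STAGES}")
    i = stage - 1
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    tn = int(cm.total - tp - fp - fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    return StageMetrics(stage, tp, fp, fn, tn, precision, recall,
                        f1_score(precision, recall), support=tp + fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Multiclass accuracy trace/N."""
    if cm.total == 0:
        raise ValidationError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


@dataclass
class MetricsReport:
    """Per-stage table plus overall accuracy and macro averages."""

    per_stage: pd.DataFrame
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int

    def to_percent_frame(self, decimals: int = 2) -> pd.DataFrame:
        """Per-stage metrics as percentages (paper-style printing)."""
        out = self.per_stage.copy()
        for col in ("precision", "recall", "f1"):
            out[col] = (out[col] * 100).round(decimals)
        return out


def evaluate(
    true_stages: Sequence[int], predicted_stages: Sequence[int]
) -> tuple[MetricsReport, ConfusionMatrix]:
    """Confusion matrix + full metrics report for paired stage labels."""
    cm = ConfusionMatrix.from_labels(true_stages, predicted_stages)
    rows = []
    for stage in STAGES:
        m = per_stage_metrics(cm, stage)
        rows.append({
            "stage": f"iCS{stage}", "support": m.support,
            "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
            "precision": m.precision, "recall": m.recall, "f1": m.f1,
        })
    table = pd.DataFrame(rows).set_index("stage")
    with np.errstate(invalid="ignore"):
        report = MetricsReport(
            per_stage=table,
            accuracy=accuracy(cm),
            macro_precision=float(np.nanmean(table["precision"])),
            macro_recall=float(np.nanmean(table["recall"])),
            macro_f1=float(np.nanmean(table["f1"])),
            n=cm.total,
        )
    return report, cm
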