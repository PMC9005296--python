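"""Confusion-matrix metrics and cross-validation protocols.

Metrics are the four standard binary-classification measures:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SN  = TP / (TP + FN)            (sensitivity, recall on positives)
    SP  = TN / (TN + FP)            (specificity, recall on negatives)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

MCC is reported as 0 (with a degenerate flag) when its denominator vanishes.
For enhancer identification the positive class is "enhancer"; for
strong/weak classification it is "strong_enhancer".

Cross-validation is stratified k-fold (default 5) with a seeded shuffle;
every sample is tested exactly once and all fitting — feature selection,
embedding training, classifier training — happens inside the training folds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .sequence_io import ConfigError, DnaSequence, LabeledDataset


class MetricsError(ValueError):
    """Invalid confusion counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricsError(f"negative confusion counts: {self}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    counts: ConfusionCounts
    degenerate_mcc: bool = False

    def to_dict(self) -> dict:
        return {
            "ACC": self.acc,
            "SN": self.sn,
            "SP": self.sp,
            "MCC": self.mcc,
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "degenerate_mcc": self.degenerate_mcc,
        }

    def pretty(self) -> str:
        return (
            f"ACC={self.acc:.4f}  SN={self.sn:.4f}  SP={self.sp:.4f}  "
            f"MCC={self.mcc:.4f}  (TP={self.counts.tp} TN={self.counts.tn} "
            f"FP={self.counts.fp} FN={self.counts.fn})"
        )


def compute_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """ACC/SN/SP/MCC from raw confusion counts (exact formulas)."""
    if counts.total == 0:
        raise MetricsError("no evaluated samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return EvaluationReport(acc, sn, sp, mcc, counts, degenerate)


def confusion_from_labels(
    y_true: Sequence[str], y_pred: Sequence[str], positive_label: str
) -> ConfusionCounts:
    """Binarize label sequences against one positive class and count."""
    if len(y_true) != len(y_pred):
        raise ConfigError("y_true and y_pred length mismatch")
    t = np.asarray([y == positive_label for y in y_true])
    p = np.asarray([y == positive_label for y in y_pred])
    return ConfusionCounts(
        tp=int((t & p).sum()),
        tn=int((~t & ~p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
    )


def mcc_from_labels(
    y_true: Sequence[str], y_pred: Sequence[str], positive_label: str
) -> float:
    return compute_metrics(confusion_from_labels(y_true, y_pred, positive_label)).mcc


class Pipeline(Protocol):
    """Anything trainable on a LabeledDataset that predicts labels."""

    def fit(self, train: LabeledDataset) -> "Pipeline": ...

    def predict(self, sequences: Sequence[DnaSequence]) -> list[str]: ...


@dataclass
class CvResult:
    fold_reports: list[EvaluationReport]
    mean: dict[str, float]
    fold_predictions: list[tuple[list[str], list[str], list[str]]]  # ids, true, pred

    def to_json(self) -> str:
        return json.dumps(
            {
                "folds": [r.to_dict() for r in self.fold_reports],
                "mean": self.mean,
            },
            indent=2,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def kfold_cv(
    dataset: LabeledDataset,
    pipeline_factory: Callable[[], Pipeline],
    positive_label: str,
    k: int = 5,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold cross-validation with seeded shuffling.

    ``pipeline_factory`` must return a fresh, unfitted pipeline per fold so
    that no state (embeddings, selected features, trained weights) leaks
    between folds.
    """
    y = np.asarray(dataset.labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < k]
    if len(too_small):
        raise ConfigError(
            f"class(es) {list(too_small)} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, predictions = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = dataset.subset(train_idx, split="train")
        test = dataset.subset(test_idx, split="test")
        model = pipeline_factory().fit(train)
        pred = model.predict(test.sequences)
        reports.append(
            compute_metrics(
                confusion_from_labels(test.labels, pred, positive_label)
            )
        )
        predictions.append(
            ([s.id for s in test.sequences], list(test.labels), list(pred))
        )
    mean = {
        m: float(np.mean([getattr(r, m.lower()) for r in reports]))
        for m in ("ACC", "SN", "SP", "MCC")
    }
    return CvResult(reports, mean, predictions)


def write_fold_predictions_tsv(result: CvResult, path: str | Path) -> None:
    lines = ["fold\tid\ttrue\tpredicted"]
    for fold, (ids, true, pred) in enumerate(result.fold_predictions):
        for i, t, p in zip(ids, true, pred):
            lines.append(f"{fold}\t{i}\t{t}\t{p}")
    Path(path).write_text("\n".join(lines) + "\n")
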