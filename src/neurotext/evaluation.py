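"""Evaluation protocol: span matching, P/R/F1, confusion, cross-validation.

NER predictions are scored under two criteria. *Exact* matching credits a
predicted span only when its boundaries equal a gold span's. *Lenient*
matching credits a predicted span when it lies within (or equals) some
gold span — predicted boundaries may be smaller than the annotation but
never larger — with each gold span creditable at most once.

Relation extraction is scored with multi-class precision/recall/F1 and a
row-normalized confusion matrix (rows = gold classes, entries = recalls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .corpus_io import kfold_splits, select_units
from .types import EntitySpan, LabeledSentence, RELATION_CLASSES

__all__ = [
    "match_spans", "prf", "EvalReport", "ner_report",
    "ConfusionMatrix", "confusion", "classification_report", "cross_validate",
]


def _check_disjoint(spans: Sequence[EntitySpan], kind: str) -> list[EntitySpan]:
    spans = sorted(spans)
    for a, b in zip(spans, spans[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping {kind} spans {a} / {b}")
    return spans


def match_spans(
    gold: Sequence[EntitySpan], pred: Sequence[EntitySpan], mode: str = "exact"
) -> tuple[int, int, int]:
    """Count (tp, fp, fn) for one sentence under exact or lenient matching.

    Lenient assignment is greedy in span order; each gold span is matched
    at most once.
    """
    if mode not in ("exact", "lenient"):
        raise ValueError(f"unknown matching mode {mode!r}")
    gold = _check_disjoint(gold, "gold")
    pred = _check_disjoint(pred, "predicted")
    if mode == "exact":
        gold_set = {(g.start, g.end) for g in gold}
        tp = sum((p.start, p.end) in gold_set for p in pred)
    else:
        used = [False] * len(gold)
        tp = 0
        for p in pred:
            for i, g in enumerate(gold):
                if not used[i] and g.contains(p):
                    used[i] = True
                    tp += 1
                    break
    return tp, len(pred) - tp, len(gold) - tp


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 with the all-zero-when-undefined convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class EvalReport:
    """Metrics for one evaluation, optionally aggregated over folds."""

    precision: float
    recall: float
    f1: float
    mode: str = "exact"
    fold_values: list[dict[str, float]] = field(default_factory=list)
    sd: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"precision": self.precision, "recall": self.recall,
               "f1": self.f1, "mode": self.mode}
        if self.fold_values:
            out["folds"] = self.fold_values
            out["sd"] = self.sd
        return out


def ner_report(
    gold: Sequence[Sequence[EntitySpan]],
    pred: Sequence[Sequence[EntitySpan]],
    mode: str = "exact",
) -> EvalReport:
    """Micro-averaged span P/R/F1 pooled over sentences."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted sentence counts differ")
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        a, b, c = match_spans(g, p, mode)
        tp, fp, fn = tp + a, fp + b, fn + c
    return EvalReport(*prf(tp, fp, fn), mode=mode)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized recalls; empty rows stay all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return np.divide(self.counts, sums, out=np.zeros_like(self.counts, dtype=float),
                         where=sums > 0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    gold_labels: Sequence[str], pred_labels: Sequence[str],
    classes: Sequence[str] = RELATION_CLASSES,
) -> ConfusionMatrix:
    """Gold x predicted count matrix in the given class order."""
    if len(gold_labels) != len(pred_labels):
        raise ValueError("label vectors differ in length")
    unknown = (set(gold_labels) | set(pred_labels)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    counts = _sk_confusion(gold_labels, pred_labels, labels=list(classes))
    return ConfusionMatrix(counts, tuple(classes))


def classification_report(
    gold_labels: Sequence[str], pred_labels: Sequence[str],
    classes: Sequence[str] = RELATION_CLASSES, average: str = "macro",
) -> EvalReport:
    """Multi-class P/R/F1 (macro by default; micro pools decisions)."""
    cm = confusion(gold_labels, pred_labels, classes)
    counts = cm.counts
    if average == "micro":
        tp = int(np.trace(counts))
        fp = fn = int(counts.sum()) - tp
        return EvalReport(*prf(tp, fp, fn), mode="micro")
    ps, rs, fs = [], [], []
    for i in range(len(classes)):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum()) - tp
        fn = int(counts[i, :].sum()) - tp
        p, r, f = prf(tp, fp, fn)
        ps.append(p), rs.append(r), fs.append(f)
    return EvalReport(float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs)), mode="macro")


def cross_validate(
    corpus: list[LabeledSentence],
    k: int,
    pipeline: Callable[[list[LabeledSentence], list[LabeledSentence]], dict[str, float]],
    seed: int = 0,
    unit_level: str = "document",
) -> EvalReport:
    """k-fold harness: each unit is tested exactly once.

    ``pipeline(train_sentences, test_sentences)`` returns a metric dict
    with at least precision/recall/f1; per-fold values and mean +/- SD
    are aggregated into the report.
    """
    folds = kfold_splits(corpus, k, unit_level=unit_level, seed=seed)
    fold_metrics = []
    for split in folds:
        train = select_units(corpus, split.train + split.validation, unit_level)
        test = select_units(corpus, split.test, unit_level)
        fold_metrics.append(pipeline(train, test))
    keys = fold_metrics[0].keys()
    mean = {k_: float(np.mean([m[k_] for m in fold_metrics])) for k_ in keys}
    sd = {k_: float(np.std([m[k_] for m in fold_metrics], ddof=1)) for k_ in keys}
    return EvalReport(
        precision=mean.get("precision", 0.0),
        recall=mean.get("recall", 0.0),
        f1=mean.get("f1", 0.0),
        mode="cv",
        fold_values=fold_metrics,
        sd=sd,
    )
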