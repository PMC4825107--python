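"""Voxel- and subject-level evaluation, and the leave-one-out harness.

Metric conventions follow the verbal definitions (sensitivity, fall-out,
precision, recall and their harmonic mean):

    TPR = TP/(TP+FN)    FPR = FP/(FP+TN)    precision = TP/(TP+FP)
    recall = TPR        F = 2*precision*recall/(precision+recall)

0/0 cases: precision is 0 when no positives are predicted; F is 0 when
precision+recall is 0; TPR (and hence recall and F) is NaN when the ground
truth contains no positives at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import classifiers as clf
from .config import PipelineConfig
from .features import NormativeModel
from .pipeline import (DetectionResult, PreparedSubject, build_training_set,
                       classify_subject, prepare_subject, train_models)
from .postprocess import SubjectCall
from .volume_io import Subject
from .voting import LabelVolume

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts", "metrics",
           "subject_metrics", "loocv_run", "FoldResult", "LoocvResult"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "voxel"

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    tpr: float
    fpr: float
    precision: float
    recall: float
    f_score: float
    counts: ConfusionCounts


def confusion_counts(pred: LabelVolume | np.ndarray,
                     truth: np.ndarray,
                     mask: Optional[np.ndarray] = None,
                     level: str = "voxel") -> ConfusionCounts:
    """Exact confusion counts over the masked voxels."""
    p = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("prediction/truth grid mismatch")
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    elif mask.shape != p.shape:
        raise ValueError("mask grid mismatch")
    p = p[mask].astype(bool)
    t = t[mask].astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        level=level,
    )


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Metric report from confusion counts; scale-free in the counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    tpr = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    fpr = fp / (fp + tn) if (fp + tn) > 0 else math.nan
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tpr
    if math.isnan(recall):
        f_score = math.nan
    elif precision + recall == 0:
        f_score = 0.0
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return MetricReport(tpr=tpr, fpr=fpr, precision=precision,
                        recall=recall, f_score=f_score, counts=counts)


def subject_metrics(calls: Sequence[SubjectCall],
                    truth_flags: Mapping[str, bool]) -> MetricReport:
    """Subject-level metrics with patient as the positive class."""
    tp = fp = fn = tn = 0
    for call in calls:
        if call.subject_id not in truth_flags:
            raise ValueError(f"unknown subject id {call.subject_id!r}")
        truth = bool(truth_flags[call.subject_id])
        pred = call.is_patient_pred
        tp += pred and truth
        fp += pred and not truth
        fn += (not pred) and truth
        tn += (not pred) and (not truth)
    return metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, level="subject"))


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation


@dataclass
class FoldResult:
    """Outputs of one LOOCV fold (one held-out subject)."""

    subject_id: str
    is_patient_true: bool
    call: SubjectCall
    detection: DetectionResult
    # (classifier_or_PUV, stage) -> voxel MetricReport; stages: raw/opened/filtered
    reports: dict[tuple[str, str], MetricReport] = field(default_factory=dict)
    fp_counts: dict[str, int] = field(default_factory=dict)
    containment_ok: bool = True


@dataclass
class LoocvResult:
    folds: list[FoldResult]
    subject_report: MetricReport
    summary: pd.DataFrame    # mean/SD of each metric per classifier/stage

    def fold(self, subject_id: str) -> FoldResult:
        return next(f for f in self.folds if f.subject_id == subject_id)


def _fold_reports(fold: FoldResult, prep: PreparedSubject) -> None:
    truth = (prep.subject.lesion_mask.data > 0 if prep.subject.lesion_mask
             is not None else np.zeros(prep.domain.shape, dtype=bool))
    det = fold.detection
    staged = {("PUV", "raw"): det.labels["PUV"],
              ("PUV", "opened"): det.opened,
              ("PUV", "filtered"): det.filtered}
    for kind, lv in det.labels.items():
        if kind != "PUV":
            staged[(kind, "raw")] = lv
    puv_pos = det.labels["PUV"].labels.astype(bool)
    for (kind, stage), lv in staged.items():
        counts = confusion_counts(lv, truth, prep.domain)
        fold.reports[(kind, stage)] = metrics(counts)
        if stage == "raw":
            fold.fp_counts[kind] = counts.fp
            if kind != "PUV":
                # unanimity: PUV positives must lie inside each voter's positives
                if np.any(puv_pos & ~lv.labels.astype(bool)):
                    fold.containment_ok = False


def loocv_run(cohort: Sequence[Subject],
              config: PipelineConfig | None = None) -> LoocvResult:
    """Leave-one-out cross-validation over a cohort.

    For each held-out subject, the normative model is rebuilt from the
    remaining controls only and the classifiers are retrained on the remaining
    subjects; the full pipeline (classification, unanimous voting, region
    refinement) is then applied to the held-out subject. Deterministic given
    ``config.seed``.
    """
    if config is None:
        config = PipelineConfig()
    if len(cohort) < 2:
        raise ValueError("LOOCV needs at least two subjects")
    prepared = [prepare_subject(s, config) for s in cohort]

    folds: list[FoldResult] = []
    for i, held_out in enumerate(prepared):
        training = prepared[:i] + prepared[i + 1:]
        train_controls = [p for p in training if not p.subject.is_patient]
        if not any(p.subject.is_patient for p in training):
            raise ValueError(
                f"fold {held_out.id}: no patient in the training set")
        if not train_controls:
            raise ValueError(
                f"fold {held_out.id}: no control for the normative model")
        normative = NormativeModel.fit([p.features for p in train_controls],
                                       window_edge=config.window_edge)
        rng = np.random.default_rng([config.seed, i])
        X, y = build_training_set(training, normative, config, rng)
        scaler, models = train_models(X, y, config)
        detection = classify_subject(held_out, normative, models, scaler, config)
        fold = FoldResult(subject_id=held_out.id,
                          is_patient_true=held_out.subject.is_patient,
                          call=detection.call, detection=detection)
        _fold_reports(fold, held_out)
        folds.append(fold)

    truth_flags = {p.id: p.subject.is_patient for p in prepared}
    subj_report = subject_metrics([f.call for f in folds], truth_flags)

    rows = []
    for f in folds:
        for (kind, stage), rep in f.reports.items():
            rows.append({"subject_id": f.subject_id, "classifier": kind,
                         "stage": stage, "tpr": rep.tpr, "fpr": rep.fpr,
                         "precision": rep.precision, "f_score": rep.f_score})
    per_subject = pd.DataFrame(rows)
    summary = (per_subject
               .groupby(["classifier", "stage"])[["f_score", "tpr", "fpr"]]
               .agg(["mean", "std"]))
    return LoocvResult(folds=folds, subject_report=subj_report, summary=summary)
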