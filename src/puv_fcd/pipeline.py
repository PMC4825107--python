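"""Orchestration of the five framework steps:
normalize -> features -> vote -> region-filter -> evaluate.

The helpers here are shared by the one-shot detection entry point
(`run_detect`, training on the whole cohort) and the leave-one-out
cross-validation harness in `evaluation`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import postprocess, volume_io
from .config import PipelineConfig
from .features import FeatureMaps, NormativeModel, assemble_feature_matrix
from .volume_io import Subject, Volume
from .voting import LabelVolume, puv_combine

logger = logging.getLogger("puv_fcd")

__all__ = ["PreparedSubject", "DetectionResult", "prepare_subject",
           "build_training_set", "train_models", "classify_subject",
           "run_detect"]


@dataclass
class PreparedSubject:
    """A subject after normalization and feature computation."""

    subject: Subject
    features: FeatureMaps

    @property
    def id(self) -> str:
        return self.subject.id

    @property
    def domain(self) -> np.ndarray:
        return self.features.domain

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.subject.volume.spacing

    def truth_labels(self, mask: np.ndarray) -> np.ndarray:
        if self.subject.lesion_mask is None:
            return np.zeros(int(mask.sum()), dtype=np.uint8)
        return (self.subject.lesion_mask.data[mask] > 0).astype(np.uint8)


@dataclass
class DetectionResult:
    """Per-subject outputs: label volumes before/after refinement, regions, call."""

    subject_id: str
    labels: dict[str, LabelVolume]      # one per classifier + "PUV"
    opened: LabelVolume
    filtered: LabelVolume
    regions: postprocess.RegionSet
    call: postprocess.SubjectCall


def _resample_subject(subject: Subject, spacing) -> Subject:
    def tri(v):
        return None if v is None else volume_io.resample_trilinear(v, spacing)

    mask = None
    if subject.lesion_mask is not None:
        m = volume_io.resample_trilinear(subject.lesion_mask, spacing)
        mask = m.with_data((m.data >= 0.5).astype(np.uint8))
    return Subject(id=subject.id, volume=tri(subject.volume),
                   pv_gm=tri(subject.pv_gm), pv_wm=tri(subject.pv_wm),
                   pv_csf=tri(subject.pv_csf), lesion_mask=mask,
                   is_patient=subject.is_patient)


def prepare_subject(subject: Subject, config: PipelineConfig) -> PreparedSubject:
    """Standardize intensity, optionally resample, and compute feature maps."""
    if subject.pv_gm is None or subject.pv_wm is None:
        raise ValueError(f"subject {subject.id}: GM and WM PV maps are required")
    if config.working_spacing_mm is not None and not np.allclose(
            subject.volume.spacing, config.working_spacing_mm):
        subject = _resample_subject(subject, config.working_spacing_mm)
    std = volume_io.standardize_intensity(
        subject.volume, config.standardize_lo, config.standardize_hi)
    subject = Subject(id=subject.id, volume=std, pv_gm=subject.pv_gm,
                      pv_wm=subject.pv_wm, pv_csf=subject.pv_csf,
                      lesion_mask=subject.lesion_mask,
                      is_patient=subject.is_patient)
    fmaps = FeatureMaps.compute(std, subject.pv_gm, subject.pv_wm,
                                zone_lo=config.zone_lo, zone_hi=config.zone_hi)
    return PreparedSubject(subject=subject, features=fmaps)


def build_training_set(training: Sequence[PreparedSubject],
                       normative: NormativeModel,
                       config: PipelineConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Stack masked feature vectors of the training subjects, then cap negatives."""
    xs, ys = [], []
    for prep in training:
        _, X = assemble_feature_matrix(prep.features, normative,
                                       config.feature_group, prep.domain)
        xs.append(X)
        ys.append(prep.truth_labels(prep.domain))
    X = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    if not (y == 1).any():
        raise ValueError("no lesional voxels in the training set")
    return clf.subsample_negatives(X, y, rng, config.neg_per_pos)


def train_models(X: np.ndarray, y: np.ndarray, config: PipelineConfig
                 ) -> tuple[Optional[clf.FeatureScaler], dict[str, clf.ClassifierModel]]:
    scaler = None
    if config.scale_features:
        scaler = clf.FeatureScaler().fit(X)
        X = scaler.transform(X)
    models = {kind: clf.fit(kind, X, y, ridge=config.ridge)
              for kind in config.classifier_kinds}
    return scaler, models


def classify_subject(prep: PreparedSubject,
                     normative: NormativeModel,
                     models: dict[str, clf.ClassifierModel],
                     scaler: Optional[clf.FeatureScaler],
                     config: PipelineConfig) -> DetectionResult:
    """Label every domain voxel with each classifier, combine by PUV, refine."""
    idx, X = assemble_feature_matrix(prep.features, normative,
                                     config.feature_group, prep.domain)
    if scaler is not None:
        X = scaler.transform(X)
    labels: dict[str, LabelVolume] = {}
    for kind, model in models.items():
        grid = np.zeros(prep.domain.shape, dtype=np.uint8)
        grid[prep.domain] = clf.predict_label(model, X, config.qda_variant)
        labels[kind] = LabelVolume(labels=grid, classifier_id=kind,
                                   domain_mask=prep.domain)
    puv = puv_combine(list(labels.values()))
    labels["PUV"] = puv
    opened, filtered, surviving = postprocess.refine(
        puv, prep.spacing, lw=config.lw, ts_mm3=config.ts_mm3,
        connectivity=config.connectivity)
    call = postprocess.subject_call(filtered, prep.id, regions=surviving)
    return DetectionResult(subject_id=prep.id, labels=labels, opened=opened,
                           filtered=filtered, regions=surviving, call=call)


def run_detect(subjects: Sequence[Subject] | str | Path,
               config: PipelineConfig,
               out_dir: Optional[str | Path] = None) -> list[DetectionResult]:
    """Train on the full cohort and classify every subject.

    ``subjects`` may be a manifest CSV path or an in-memory cohort. Requires
    at least one control (for the normative model) and one patient (for the
    positive class). All intermediates are persisted when ``out_dir`` is set.
    """
    t0 = time.monotonic()
    if isinstance(subjects, (str, Path)):
        subjects = volume_io.load_cohort(subjects)
    controls = [s for s in subjects if not s.is_patient]
    if not controls:
        raise ValueError("at least one control is required for the normative model")

    prepared = [prepare_subject(s, config) for s in subjects]
    logger.info("prepared %d subjects in %.1fs", len(prepared), time.monotonic() - t0)

    # normalization sanity check against the first control
    reference = next(p for p in prepared if not p.subject.is_patient)
    for p in prepared:
        if p is reference:
            continue
        try:
            overlap = volume_io.histogram_peak_overlap(
                p.subject.volume, reference.subject.volume)
        except ValueError as exc:
            logger.warning("subject %s: peak overlap check skipped (%s)", p.id, exc)
            continue
        if overlap < 0.9:
            logger.warning("subject %s: histogram peak overlap %.3f < 0.9",
                           p.id, overlap)

    normative = NormativeModel.fit(
        [p.features for p in prepared if not p.subject.is_patient],
        window_edge=config.window_edge)
    rng = np.random.default_rng(config.seed)
    X, y = build_training_set(prepared, normative, config, rng)
    scaler, models = train_models(X, y, config)
    logger.info("trained %d classifiers on %d voxels", len(models), len(y))

    results = [classify_subject(p, normative, models, scaler, config)
               for p in prepared]
    logger.info("classified cohort in %.1fs", time.monotonic() - t0)

    if out_dir is not None:
        _persist(results, prepared, config, Path(out_dir))
    return results


def _persist(results: Sequence[DetectionResult],
             prepared: Sequence[PreparedSubject],
             config: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    region_frames, call_rows = [], []
    for res, prep in zip(results, prepared):
        spacing = prep.spacing
        for name, lv in res.labels.items():
            volume_io.save_volume(Volume(lv.labels, spacing),
                                  out_dir / f"{res.subject_id}_label_{name}.nii",
                                  dtype=np.uint8)
        volume_io.save_volume(Volume(res.filtered.labels, spacing),
                              out_dir / f"{res.subject_id}_label_PUV_refined.nii",
                              dtype=np.uint8)
        region_frames.append(res.regions.to_frame(res.subject_id))
        call_rows.append({"subject_id": res.subject_id,
                          "is_patient_pred": res.call.is_patient_pred})
    regions = (pd.concat(region_frames, ignore_index=True) if region_frames
               else pd.DataFrame())
    regions.to_csv(out_dir / "regions.csv", index=False)
    pd.DataFrame(call_rows).to_csv(out_dir / "subject_calls.csv", index=False)
    log = {"config": config.to_dict(), "config_hash": config.config_hash,
           "n_subjects": len(results), "seed": config.seed}
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
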