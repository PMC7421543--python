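"""End-to-end orchestration: recording -> features -> model -> AHI.

Ties the stages together the way the method runs on a cohort: beat-level
analysis of every recording, movement truncation, a sleep stager and feature
normalization fitted on the training split only, masked training of the
sequence classifier, correction-coefficient and probability-threshold fitting
on the training recordings, and AHI estimation for everyone.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import ahi as ahi_mod
from . import features as feat_mod
from . import labeling as lab_mod
from . import model as model_mod
from .io_core import AnnotationSet, EpochGrid, Recording, make_epoch_grid
from .pulse import (
    DEFAULT_QUALITY_THRESHOLD,
    IBISeries,
    PulseSeries,
    RespSurrogate,
    analyse_rppg,
    extract_ibis,
    respiratory_surrogate,
)


@dataclass
class RecordingFeatures:
    """Everything derived from one recording up to (but excluding) staging."""

    recording_id: str
    grid: EpochGrid
    pulses: PulseSeries
    ibis: IBISeries
    resp: RespSurrogate
    counts: np.ndarray
    matrix: feat_mod.EpochFeatureMatrix  # raw values, no stage probabilities yet
    truncation: tuple[int, int]


def extract_recording_features(
    recording: Recording,
    registry: Optional[Sequence[feat_mod.FeatureSpec]] = None,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> RecordingFeatures:
    grid = make_epoch_grid(recording.duration)
    pulses = analyse_rppg(recording.rppg.samples, recording.rppg.rate, quality_threshold)
    ibis = extract_ibis(pulses, quality_threshold)
    resp = respiratory_surrogate(pulses, quality_threshold)
    if recording.accel is not None:
        counts = feat_mod.activity_counts(
            recording.accel.samples, recording.accel.rate, grid
        )
        try:
            trunc = feat_mod.truncate_recording(counts, grid)
        except ValueError:
            trunc = (0, grid.n_epochs)
    else:
        counts = np.zeros(grid.n_epochs)
        trunc = (0, grid.n_epochs)
    matrix = feat_mod.build_feature_matrix(ibis, resp, counts, grid, registry)
    return RecordingFeatures(
        recording_id=recording.id,
        grid=grid,
        pulses=pulses,
        ibis=ibis,
        resp=resp,
        counts=counts,
        matrix=matrix,
        truncation=trunc,
    )


def concat_epoch_matrices(
    matrices: Sequence[feat_mod.EpochFeatureMatrix],
) -> feat_mod.EpochFeatureMatrix:
    names = matrices[0].feature_names
    for m in matrices:
        if m.feature_names != names:
            raise ValueError("feature columns differ between recordings")
    return feat_mod.EpochFeatureMatrix(
        np.vstack([m.values for m in matrices]),
        np.vstack([m.defined_mask for m in matrices]),
        list(names),
    )


@dataclass
class FittedPipeline:
    stage_classifier: feat_mod.StageClassifier
    normalization: feat_mod.NormalizationParams
    model: model_mod.TrainedModel
    coefficient: float
    threshold: float
    registry_names: list[str] = field(default_factory=list)

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "FittedPipeline":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class CohortStudyResult:
    fitted: FittedPipeline
    recording_ids: list[str]
    reference_ahis: np.ndarray
    estimated_ahis: np.ndarray
    tst_minutes: np.ndarray
    probabilities: list[np.ndarray]
    labels: list[np.ndarray]
    weights: list[np.ndarray]
    sleep_masks: list[np.ndarray]
    train_indices: list[int]


def _epoch_weights(rf: RecordingFeatures) -> np.ndarray:
    w = lab_mod.zero_weight_mask(rf.matrix.coverage_feature)
    start, stop = rf.truncation
    w[:start] = 0.0
    w[stop:] = 0.0
    return w


def run_cohort_study(
    cohort: Sequence[tuple[Recording, AnnotationSet, object]],
    n_train: int,
    seed: int = 0,
    model_overrides: Optional[dict] = None,
    threshold_mode: str = "severity_kappa",
    features_cache: Optional[Sequence[RecordingFeatures]] = None,
) -> CohortStudyResult:
    """Train on the first ``n_train`` recordings, estimate the AHI for all.

    The sleep stager, feature normalization, sequence classifier, correction
    coefficient and probability threshold are all fitted on the training
    split only; the remaining recordings act as the validation split for
    early stopping and are never used for any fit.
    """
    recs = [c[0] for c in cohort]
    anns = [c[1] for c in cohort]
    if not 1 <= n_train < len(recs):
        raise ValueError("n_train must leave at least one validation recording")

    feats = (
        list(features_cache)
        if features_cache is not None
        else [extract_recording_features(r) for r in recs]
    )
    train_idx = list(range(n_train))
    val_idx = list(range(n_train, len(recs)))

    stager = feat_mod.StageClassifier().fit(
        [feats[i].matrix for i in train_idx],
        [anns[i].hypnogram for i in train_idx],
    )
    norm = feat_mod.fit_normalization(
        concat_epoch_matrices([feats[i].matrix for i in train_idx])
    )

    inputs, labels, weights, sleep_masks, tsts = [], [], [], [], []
    for rf, ann in zip(feats, anns):
        mat = feat_mod.apply_normalization(rf.matrix, norm)
        mat.stage_probs = feat_mod.sleep_stage_probabilities(rf.matrix, stager)
        inputs.append(feat_mod.model_input(mat))
        labels.append(
            lab_mod.label_re_epochs(ann.respiratory_events(), rf.grid).astype(float)
        )
        weights.append(_epoch_weights(rf))
        tst, sm = ahi_mod.estimate_tst(mat.stage_probs)
        tsts.append(tst)
        sleep_masks.append(sm)

    cfg = model_mod.ModelConfig(
        input_dim=inputs[0].shape[1],
        seed=seed,
        **(model_overrides or {}),
    )
    net = model_mod.build_model(cfg)
    net = model_mod.train(
        net,
        [inputs[i] for i in train_idx],
        [labels[i] for i in train_idx],
        [weights[i] for i in train_idx],
        val_features=[inputs[i] for i in val_idx],
        val_labels=[labels[i] for i in val_idx],
        val_weights=[weights[i] for i in val_idx],
    )
    probs = model_mod.predict_probabilities(net, inputs)

    raw_ref = [
        ahi_mod.reference_epoch_ahi(labels[i], sleep_masks[i], weights[i], tsts[i])
        for i in train_idx
    ]
    ref_train = [anns[i].reference_ahi for i in train_idx]
    coefficient = ahi_mod.fit_correction_coefficient(ref_train, raw_ref)

    threshold = model_mod.select_threshold(
        [probs[i] for i in train_idx],
        ref_train,
        [sleep_masks[i] for i in train_idx],
        [weights[i] for i in train_idx],
        [tsts[i] for i in train_idx],
        coefficient=coefficient,
        mode=threshold_mode,
        labels=[labels[i] for i in train_idx],
    )
    net.threshold = threshold

    estimated = np.array(
        [
            ahi_mod.estimate_ahi(
                probs[i], threshold, sleep_masks[i], weights[i], tsts[i], coefficient
            ).estimated_ahi
            for i in range(len(recs))
        ]
    )
    fitted = FittedPipeline(
        stage_classifier=stager,
        normalization=norm,
        model=net,
        coefficient=coefficient,
        threshold=threshold,
        registry_names=list(feats[0].matrix.feature_names),
    )
    return CohortStudyResult(
        fitted=fitted,
        recording_ids=[r.id for r in recs],
        reference_ahis=np.array([a.reference_ahi for a in anns], dtype=float),
        estimated_ahis=estimated,
        tst_minutes=np.array(tsts),
        probabilities=probs,
        labels=labels,
        weights=weights,
        sleep_masks=sleep_masks,
        train_indices=train_idx,
    )


def estimate_recording(
    fitted: FittedPipeline, recording: Recording
) -> tuple[ahi_mod.AHIResult, ahi_mod.QualityReport]:
    """Apply a fitted pipeline to a single new recording."""
    rf = extract_recording_features(recording)
    mat = feat_mod.apply_normalization(rf.matrix, fitted.normalization)
    mat.stage_probs = feat_mod.sleep_stage_probabilities(rf.matrix, fitted.stage_classifier)
    x = feat_mod.model_input(mat)
    probs = model_mod.predict_probabilities(fitted.model, [x])[0]
    tst, sleep_mask = ahi_mod.estimate_tst(mat.stage_probs)
    weights = _epoch_weights(rf)
    result = ahi_mod.estimate_ahi(
        probs, fitted.threshold, sleep_mask, weights, tst, fitted.coefficient
    )
    quality = ahi_mod.quality_report(rf.pulses, rf.ibis, rf.grid)
    return result, quality
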