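"""End-to-end orchestration of the four-stage detection pipeline.

Per image: tile (when larger than the detector's working size) -> detect
candidates -> map to global coordinates and suppress duplicates ->
compute handcrafted features per candidate -> threshold cascade ->
two-scorer hierarchical fusion -> (optionally) evaluate against ground
truth. Per-stage candidate counts are logged and returned; each stage can
only remove candidates, so the counts are monotone non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import CentroidAnnotation
from .errors import CalibrationRequiredError, DataError
from .evaluation import (
    ICPR2012_CRITERION,
    ICPR2014_CRITERION,
    EvalCounts,
    MatchCriterion,
    PRF,
    match_detections,
    prf_metrics,
)
from .features import FeatureBundle, compute_features
from .filtering import (
    FeatureFamily,
    FilterCascade,
    ThresholdObjective,
    apply_cascade,
    calibrate_cascade,
)
from .fusion import (
    Combiner,
    FusionConfig,
    FusionObjective,
    LogisticFeatureScorer,
    ScorerOutput,
    calibrate_fusion,
    fuse_scores,
    hierarchical_classify,
)
from .geometry import (
    Detection,
    ReferenceDetectorConfig,
    Stage,
    nms,
    reference_detector,
)
from .io import PipelineConfig
from .tiling import KeepRule, extract_patches, patch_to_global

__all__ = [
    "PipelineCalibration",
    "StageCounts",
    "ImageResult",
    "PipelineReport",
    "calibrate_pipeline",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

# feature-family split of the two reference scorers: intensity/color
# evidence versus texture/shape evidence
SCORER_A_FAMILIES = ("stats", "color")
SCORER_B_FAMILIES = ("lbp", "hog")


@dataclass
class PipelineCalibration:
    """Everything the inference pipeline needs from training data."""

    cascade: FilterCascade
    fusion_config: FusionConfig
    scorer_a: LogisticFeatureScorer
    scorer_b: LogisticFeatureScorer


@dataclass(frozen=True)
class StageCounts:
    """Candidate counts after each pipeline stage (non-increasing)."""

    detector: int
    filtered: int
    fused: int


@dataclass
class ImageResult:
    image_id: str
    detections: list[Detection]
    stage_counts: StageCounts
    counts: EvalCounts | None = None


@dataclass
class PipelineReport:
    images: list[ImageResult] = field(default_factory=list)

    @property
    def detections(self) -> list[Detection]:
        return [d for r in self.images for d in r.detections]

    def aggregate_counts(self) -> EvalCounts | None:
        per_image = [r.counts for r in self.images if r.counts is not None]
        if not per_image:
            return None
        return EvalCounts(
            tp=sum(c.tp for c in per_image),
            fp=sum(c.fp for c in per_image),
            fn=sum(c.fn for c in per_image),
        )

    def aggregate_prf(self) -> PRF | None:
        counts = self.aggregate_counts()
        return None if counts is None else prf_metrics(counts)


def _detector_config(config: PipelineConfig) -> ReferenceDetectorConfig:
    d = config.detector
    return ReferenceDetectorConfig(
        darkness_threshold=d.darkness_threshold,
        min_area=d.min_area,
        max_area=d.max_area,
        box_size=d.box_size,
        nms_threshold=d.output_nms_threshold,
    )


def _criterion(config: PipelineConfig) -> MatchCriterion:
    return (
        ICPR2012_CRITERION
        if config.evaluation.criterion == "icpr2012"
        else ICPR2014_CRITERION
    )


def _detect_candidates(image: np.ndarray, config: PipelineConfig) -> list[Detection]:
    """Candidate detections in global coordinates, tiling large images."""
    det_cfg = _detector_config(config)
    h, w = image.shape[:2]
    patch = config.tiling.patch_size
    if h <= patch and w <= patch:
        return reference_detector(image, det_cfg)
    dets: list[Detection] = []
    for spec, raster, _ in extract_patches(
        image, [], patch_size=patch, stride=config.tiling.scan_stride,
        keep_rule=KeepRule.ALL,
    ):
        local = reference_detector(raster, det_cfg)
        dets.extend(patch_to_global(spec, local, image_shape=(h, w)))
    return nms(dets, det_cfg.nms_threshold)


def _candidate_patch(image: np.ndarray, det: Detection) -> np.ndarray:
    b = det.box
    h, w = image.shape[:2]
    x0, y0 = max(0, int(b.x_min)), max(0, int(b.y_min))
    x1, y1 = min(w, int(np.ceil(b.x_max))), min(h, int(np.ceil(b.y_max)))
    return image[y0:y1, x0:x1]


def _featurize(
    image: np.ndarray, detections: Sequence[Detection]
) -> list[tuple[Detection, FeatureBundle]]:
    return [(d, compute_features(_candidate_patch(image, d))) for d in detections]


def _label_candidates(
    detections: Sequence[Detection],
    truth: Sequence[CentroidAnnotation],
    criterion: MatchCriterion,
) -> list[int]:
    """1 for candidates matched one-to-one to a mitotic truth centroid."""
    mitotic = [t for t in truth if t.class_label in (None, "mitotic")]
    _, matches = match_detections(
        [d.centroid for d in detections],
        [(t.x, t.y) for t in mitotic],
        criterion,
    )
    matched = {i for i, _ in matches}
    return [1 if i in matched else 0 for i in range(len(detections))]


def calibrate_pipeline(
    training: Sequence[tuple[str, np.ndarray, Sequence[CentroidAnnotation]]],
    config: PipelineConfig,
) -> PipelineCalibration:
    """Calibrate cascade thresholds, reference scorers, and fusion thresholds.

    Candidates are detected on each training image and labeled mitotic
    when they match an annotated mitotic centroid under the evaluation
    criterion; the labeled feature bundles drive cascade calibration, the
    two logistic scorers are fitted on the same candidates, and fusion
    thresholds are grid-searched on the scores of the cascade survivors.
    """
    criterion = _criterion(config)
    labeled: list[tuple[Detection, FeatureBundle, int]] = []
    for image_id, image, annotations in training:
        dets = _detect_candidates(image, config)
        labels = _label_candidates(dets, annotations, criterion)
        for (det, bundle), lab in zip(_featurize(image, dets), labels):
            labeled.append((det, bundle, lab))
    if not labeled:
        raise DataError("no candidates detected on the training images")
    bundles_labels = [(b, lab) for _, b, lab in labeled]

    cascade = calibrate_cascade(
        bundles_labels,
        recall_retention=config.filter.recall_retention,
        stage_order=[FeatureFamily(f) for f in config.filter.stage_order],
        objective=ThresholdObjective(config.filter.objective),
    )
    scorer_a = LogisticFeatureScorer(SCORER_A_FAMILIES).fit(bundles_labels)
    scorer_b = LogisticFeatureScorer(SCORER_B_FAMILIES).fit(bundles_labels)

    accepted, _ = apply_cascade([(d, b) for d, b, _ in labeled], cascade)
    surv_bundles = [b for _, b in accepted]
    surv_labels = _survivor_labels(labeled, cascade)
    if len(set(surv_labels)) < 2:  # cascade removed a whole class: use all
        surv_bundles = [b for _, b, _ in labeled]
        surv_labels = [lab for _, _, lab in labeled]
    sa = scorer_a.score(surv_bundles)
    sb = scorer_b.score(surv_bundles)
    fusion_training = [
        (ScorerOutput(float(a), float(b)), lab)
        for a, b, lab in zip(sa, sb, surv_labels)
    ]
    fusion_config = calibrate_fusion(
        fusion_training,
        objective=FusionObjective(config.fusion.objective),
        weight_a=config.fusion.weight_a,
        combiner=Combiner(config.fusion.combiner),
    )
    return PipelineCalibration(
        cascade=cascade,
        fusion_config=fusion_config,
        scorer_a=scorer_a,
        scorer_b=scorer_b,
    )


def _survivor_labels(
    labeled: Sequence[tuple[Detection, FeatureBundle, int]],
    cascade: FilterCascade,
) -> list[int]:
    accepted, _ = apply_cascade([(d, b) for d, b, _ in labeled], cascade)
    accepted_ids = {id(b) for _, b in accepted}
    return [lab for _, b, lab in labeled if id(b) in accepted_ids]


def run_pipeline(
    config: PipelineConfig,
    items: Sequence[tuple[str, np.ndarray, Sequence[CentroidAnnotation] | None]],
    calibration: PipelineCalibration,
) -> PipelineReport:
    """Run the calibrated pipeline on images, evaluating where truth is given.

    The run is a pure function of (config, calibration, inputs); every
    stochastic component was fixed at calibration time.
    """
    if calibration is None:
        raise CalibrationRequiredError("run_pipeline needs a PipelineCalibration")
    criterion = _criterion(config)
    report = PipelineReport()
    for image_id, image, annotations in items:
        candidates = _detect_candidates(image, config)
        featurized = _featurize(image, candidates)
        accepted, _ = apply_cascade(featurized, calibration.cascade)

        fused: list[Detection] = []
        if accepted:
            bundles = [b for _, b in accepted]
            sa = calibration.scorer_a.score(bundles)
            sb = calibration.scorer_b.score(bundles)
            for (det, _), a, b in zip(accepted, sa, sb):
                out = ScorerOutput(float(a), float(b))
                is_mitotic, _ = hierarchical_classify(out, calibration.fusion_config)
                if is_mitotic:
                    fused.append(
                        Detection(
                            box=det.box,
                            centroid=det.centroid,
                            score=fuse_scores(out, calibration.fusion_config),
                            stage=Stage.FUSED,
                            image_id=image_id,
                        )
                    )
        counts = None
        if annotations is not None:
            mitotic = [t for t in annotations if t.class_label in (None, "mitotic")]
            counts, _ = match_detections(
                [d.centroid for d in fused],
                [(t.x, t.y) for t in mitotic],
                criterion,
            )
        stage_counts = StageCounts(
            detector=len(candidates), filtered=len(accepted), fused=len(fused)
        )
        logger.info(
            "%s: detector=%d filtered=%d fused=%d",
            image_id, stage_counts.detector, stage_counts.filtered, stage_counts.fused,
        )
        report.images.append(
            ImageResult(
                image_id=image_id,
                detections=fused,
                stage_counts=stage_counts,
                counts=counts,
            )
        )
    return report
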