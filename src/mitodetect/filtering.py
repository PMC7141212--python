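"""False-positive reduction by a sequential per-feature threshold cascade.

Candidate detections are compared, one feature family at a time, against a
threshold calibrated on labeled training candidates; a candidate must pass
every stage to survive. Vector-valued families (LBP, HOG, color, and the
4-vector of first-order statistics) are reduced to a scalar by similarity
to the mitotic-class template (the mean feature vector of the mitotic
training candidates): cosine similarity for dense descriptors, histogram
intersection for normalized histograms. The calibrated threshold of each
stage is chosen to retain a configured fraction of the mitotic candidates
that survived the previous stages, which mirrors the stage's purpose —
discard clear non-mitoses while keeping essentially all true mitoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import CalibrationRequiredError, ConfigError, DataError
from .features import FeatureBundle
from .geometry import Detection, Stage

__all__ = [
    "FeatureFamily",
    "Scalarizer",
    "Direction",
    "FilterStage",
    "FilterCascade",
    "ThresholdObjective",
    "scalar_score",
    "calibrate_cascade",
    "apply_cascade",
    "DEFAULT_STAGE_ORDER",
]


class FeatureFamily(str, Enum):
    STATS = "stats"
    LBP = "lbp"
    HOG = "hog"
    COLOR = "color"


class Scalarizer(str, Enum):
    COSINE_TO_TEMPLATE = "cosine_to_template"
    HISTOGRAM_INTERSECTION_TO_TEMPLATE = "histogram_intersection_to_template"
    RAW_COMPONENT = "raw_component"


class Direction(str, Enum):
    ACCEPT_IF_GE = "accept_if_ge"
    ACCEPT_IF_LE = "accept_if_le"


class ThresholdObjective(str, Enum):
    """Threshold selection rule: retain a recall fraction, or maximize F1."""

    RECALL_RETENTION = "recall_retention"
    MAX_F1 = "max_f1"


# presentation order of the four families: statistics, texture, shape, color
DEFAULT_STAGE_ORDER: tuple[FeatureFamily, ...] = (
    FeatureFamily.STATS,
    FeatureFamily.LBP,
    FeatureFamily.HOG,
    FeatureFamily.COLOR,
)

_DEFAULT_SCALARIZER = {
    FeatureFamily.STATS: Scalarizer.COSINE_TO_TEMPLATE,
    FeatureFamily.LBP: Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE,
    FeatureFamily.HOG: Scalarizer.COSINE_TO_TEMPLATE,
    FeatureFamily.COLOR: Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE,
}


@dataclass(frozen=True)
class FilterStage:
    """One cascade stage: a feature family, how it is scalarized, and the
    calibrated accept threshold with its direction."""

    feature_family: FeatureFamily
    scalarizer: Scalarizer
    threshold: float
    direction: Direction = Direction.ACCEPT_IF_GE
    component_index: int | None = None  # for RAW_COMPONENT on stats

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ConfigError("stage threshold must be finite")
        if (
            self.scalarizer is Scalarizer.RAW_COMPONENT
            and self.feature_family is not FeatureFamily.STATS
        ):
            raise ConfigError("raw_component scalarizer only applies to stats")

    def accepts(self, score: float) -> bool:
        if self.direction is Direction.ACCEPT_IF_GE:
            return score >= self.threshold
        return score <= self.threshold


@dataclass
class FilterCascade:
    """Ordered stages plus the per-family mitotic-class templates."""

    stages: list[FilterStage] = field(default_factory=list)
    templates: dict[FeatureFamily, np.ndarray] = field(default_factory=dict)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def scalar_score(
    bundle: FeatureBundle,
    stage: FilterStage,
    templates: dict[FeatureFamily, np.ndarray],
) -> float:
    """Scalar feature value of a candidate under one cascade stage."""
    vec = bundle.family(stage.feature_family.value)
    if stage.scalarizer is Scalarizer.RAW_COMPONENT:
        if stage.component_index is None:
            raise ConfigError("raw_component stage needs component_index")
        return float(vec[stage.component_index])
    template = templates.get(stage.feature_family)
    if template is None:
        raise CalibrationRequiredError(
            f"no template for feature family {stage.feature_family.value!r}"
        )
    if stage.scalarizer is Scalarizer.COSINE_TO_TEMPLATE:
        return _cosine(vec, template)
    if stage.scalarizer is Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE:
        return float(np.minimum(vec, template).sum())
    raise ConfigError(f"unknown scalarizer {stage.scalarizer!r}")


def _retention_threshold(
    pos_scores: np.ndarray,
    neg_scores: np.ndarray,
    retention: float,
    direction: Direction,
) -> float:
    """Threshold retaining >= retention of positive scores on training data.

    The anchor is the score of the last retained positive (the retention
    quantile). With retention 1.0 and no separation margin that would sit
    exactly on the minimum positive, so a held-out positive drawn from the
    same distribution fails the stage about half the time it lands below
    the training minimum. To generalize, the threshold is placed in the
    middle of the gap between the anchor and the nearest negative on the
    reject side (or slightly beyond the anchor when no negative lies
    there). Training retention is preserved; only the margin changes.
    """
    s = np.sort(pos_scores)
    n = len(s)
    drop = int(np.floor((1.0 - retention) * n))
    spread = float(s.std())
    if direction is Direction.ACCEPT_IF_GE:
        anchor = float(s[drop])  # drop at most the `drop` lowest positives
        below = neg_scores[neg_scores < anchor]
        return float((anchor + below.max()) / 2.0) if below.size else anchor - 3.0 * spread
    anchor = float(s[n - 1 - drop])
    above = neg_scores[neg_scores > anchor]
    return float((anchor + above.min()) / 2.0) if above.size else anchor + 3.0 * spread


def _f1_threshold(
    pos: np.ndarray, neg: np.ndarray, direction: Direction
) -> float:
    """Threshold maximizing training F1 over the candidate score values."""
    candidates = np.unique(np.concatenate([pos, neg]))
    best_t, best_f1 = float(candidates[0]), -1.0
    for t in candidates:
        if direction is Direction.ACCEPT_IF_GE:
            tp, fp = int((pos >= t).sum()), int((neg >= t).sum())
        else:
            tp, fp = int((pos <= t).sum()), int((neg <= t).sum())
        fn = len(pos) - tp
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def calibrate_cascade(
    training: Sequence[tuple[FeatureBundle, int]],
    recall_retention: float = 0.99,
    stage_order: Sequence[FeatureFamily] = DEFAULT_STAGE_ORDER,
    objective: ThresholdObjective = ThresholdObjective.RECALL_RETENTION,
) -> FilterCascade:
    """Calibrate templates and per-stage thresholds from labeled candidates.

    Templates are the mean feature vectors over mitotic (label 1)
    candidates. Stages are calibrated sequentially: each stage sees only
    the candidates that survived the previous stages, its accept direction
    is chosen so the mitotic class lies on the accept side (by comparing
    class means), and its threshold either retains ``recall_retention`` of
    the surviving mitoses (default) or maximizes training F1. The result
    is deterministic given the input order.
    """
    labels = np.array([int(lab) for _, lab in training])
    if not ((labels == 1).any() and (labels == 0).any()):
        raise DataError("calibration needs both mitotic and non-mitotic candidates")
    if not (0.0 < recall_retention <= 1.0):
        raise ConfigError(f"recall_retention {recall_retention} outside (0, 1]")

    bundles = [b for b, _ in training]
    templates = {
        fam: np.mean(
            [b.family(fam.value) for b, lab in training if lab == 1], axis=0
        )
        for fam in FeatureFamily
    }

    cascade = FilterCascade(stages=[], templates=templates)
    alive = np.ones(len(bundles), dtype=bool)
    for fam in stage_order:
        probe = FilterStage(
            feature_family=fam, scalarizer=_DEFAULT_SCALARIZER[fam], threshold=0.0
        )
        scores = np.array(
            [scalar_score(b, probe, templates) for b in bundles]
        )
        pos = scores[alive & (labels == 1)]
        neg = scores[alive & (labels == 0)]
        if len(pos) == 0:
            break  # no surviving positives to calibrate against
        direction = (
            Direction.ACCEPT_IF_GE
            if len(neg) == 0 or pos.mean() >= neg.mean()
            else Direction.ACCEPT_IF_LE
        )
        if objective is ThresholdObjective.MAX_F1 and len(neg):
            threshold = _f1_threshold(pos, neg, direction)
        else:
            threshold = _retention_threshold(pos, neg, recall_retention, direction)
        stage = FilterStage(
            feature_family=fam,
            scalarizer=_DEFAULT_SCALARIZER[fam],
            threshold=threshold,
            direction=direction,
        )
        cascade.stages.append(stage)
        alive &= np.array([stage.accepts(s) for s in scores])
    return cascade


def apply_cascade(
    candidates: Sequence[tuple[Detection, FeatureBundle]],
    cascade: FilterCascade,
) -> tuple[list[tuple[Detection, FeatureBundle]], list[tuple[Detection, FeatureBundle, int]]]:
    """Partition candidates into accepted and rejected-with-stage.

    A candidate is accepted iff it passes every stage in order; evaluation
    short-circuits at the first failing stage, whose index (0-based) tags
    the rejection. Accepted detections carry the ``filtered`` stage mark.
    """
    accepted: list[tuple[Detection, FeatureBundle]] = []
    rejected: list[tuple[Detection, FeatureBundle, int]] = []
    for det, bundle in candidates:
        failed_at = -1
        for i, stage in enumerate(cascade.stages):
            if not stage.accepts(scalar_score(bundle, stage, cascade.templates)):
                failed_at = i
                break
        if failed_at < 0:
            accepted.append((det.with_stage(Stage.FILTERED), bundle))
        else:
            rejected.append((det, bundle, failed_at))
    return accepted, rejected
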