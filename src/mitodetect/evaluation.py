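"""Contest-style detection evaluation and Nottingham mitotic grading.

A detection counts as a true positive when its centroid lies strictly
closer than a pixel distance criterion to an unmatched ground-truth
centroid (20 px for the 2012-contest convention at 0.2456 um/px, 32 px for
the 2014 convention). Matching is greedy nearest-first and one-to-one.
Precision, recall and F1 follow from the TP/FP/FN counts, and the
Nottingham mitotic-count score maps the summed count over ten high-power
fields onto grade bands 1-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "EvalCounts",
    "MatchCriterion",
    "PRF",
    "ICPR2012_CRITERION",
    "ICPR2014_CRITERION",
    "match_detections",
    "prf_metrics",
    "f1_from_precision_recall",
    "mitotic_grade",
]


@dataclass(frozen=True)
class EvalCounts:
    """True-positive / false-positive / false-negative counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise DataError("negative evaluation counts")


@dataclass(frozen=True)
class MatchCriterion:
    """Centroid-distance criterion: a detection matches a ground truth when
    their Euclidean distance is strictly less than ``max_distance``."""

    max_distance: float

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ConfigError("max_distance must be positive")


ICPR2012_CRITERION = MatchCriterion(max_distance=20.0)  # 5 um at 0.2456 um/px
ICPR2014_CRITERION = MatchCriterion(max_distance=32.0)  # 8 um


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 with a flag for the degenerate 0/0 convention."""

    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def match_detections(
    detected: Sequence[tuple[float, float]],
    truth: Sequence[tuple[float, float]],
    criterion: MatchCriterion = ICPR2012_CRITERION,
) -> tuple[EvalCounts, list[tuple[int, int]]]:
    """Greedy one-to-one centroid matching under a distance criterion.

    Candidate pairs closer than ``max_distance`` are matched in order of
    increasing distance (ties broken by detection index, then truth
    index); each detection and each truth is used at most once. Matched
    pairs are TPs, unmatched detections FPs, unmatched truths FNs.
    Returns the counts and the matched ``(detection_index, truth_index)``
    pairs.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, (dx, dy) in enumerate(detected):
        for j, (tx, ty) in enumerate(truth):
            d = float(np.hypot(dx - tx, dy - ty))
            if d < criterion.max_distance:
                pairs.append((d, i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        matches.append((i, j))
    tp = len(matches)
    return EvalCounts(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp), matches


def prf_metrics(counts: EvalCounts) -> PRF:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R).

    Any 0/0 ratio is reported as 0 with the degenerate flag set.
    """
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        return PRF(precision, recall, 0.0, degenerate=True)
    f1 = 2 * precision * recall / (precision + recall)
    return PRF(precision, recall, f1, degenerate=degenerate)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean ``2PR/(P+R)`` of a precision/recall pair; 0 when both are 0."""
    if precision < 0 or recall < 0:
        raise DataError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def mitotic_grade(counts_per_hpf: Sequence[int], expected_fields: int = 10) -> int:
    """Nottingham mitotic-count score over high-power fields.

    The per-field mitotic counts are summed; a total of 0-9 scores 1,
    10-19 scores 2, and 20 or more scores 3.
    """
    if expected_fields is not None and len(counts_per_hpf) != expected_fields:
        raise DataError(
            f"expected {expected_fields} per-field counts, got {len(counts_per_hpf)}"
        )
    counts = [int(c) for c in counts_per_hpf]
    if any(c < 0 for c in counts):
        raise DataError("negative per-field mitotic count")
    total = sum(counts)
    if total <= 9:
        return 1
    if total <= 19:
        return 2
    return 3
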