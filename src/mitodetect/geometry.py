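"""Box geometry for candidate detection.

Axis-aligned boxes, anchor generation, box-regression encoding/decoding,
IoU, greedy non-maximum suppression, the two-term detection loss used to
train region-proposal detectors, and a deterministic blob-based reference
detector that stands behind the pluggable candidate-detector interface.

Coordinate convention (used everywhere in this package): 0-based pixel
coordinates, ``x`` is the column, ``y`` the row; boxes are half-open
intervals ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigError, InvalidGeometryError

__all__ = [
    "Box",
    "BoxRegressionVector",
    "Detection",
    "DetectionLossInputs",
    "Stage",
    "ReferenceDetectorConfig",
    "encode_box_regression",
    "decode_box_regression",
    "iou",
    "nms",
    "generate_anchors",
    "detection_loss",
    "propose_and_filter",
    "reference_detector",
]

_EPS = 1e-12  # probability clamp for the log loss


class Stage(str, Enum):
    """Pipeline stage that produced (or last touched) a detection."""

    DETECTOR = "detector"
    FILTERED = "filtered"
    FUSED = "fused"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates, half-open on both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidGeometryError(
                f"degenerate box: ({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    @classmethod
    def from_center(cls, x: float, y: float, w: float, h: float) -> "Box":
        """Build a box from its center/width/height view."""
        if w <= 0 or h <= 0:
            raise InvalidGeometryError(f"non-positive box size w={w}, h={h}")
        return cls(x - w / 2.0, y - h / 2.0, x + w / 2.0, y + h / 2.0)


@dataclass(frozen=True)
class BoxRegressionVector:
    """Scale-invariant translation (vx, vy) and log-space size change (vw, vh)
    that carries an anchor box onto a proposal box."""

    vx: float
    vy: float
    vw: float
    vh: float

    def __post_init__(self) -> None:
        for name in ("vx", "vy", "vw", "vh"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidGeometryError(f"non-finite regression component {name}")

    def as_array(self) -> np.ndarray:
        return np.array([self.vx, self.vy, self.vw, self.vh], dtype=float)


@dataclass(frozen=True)
class Detection:
    """A scored candidate: box, centroid, probability, and provenance stage.

    The centroid defaults to the box center; annotation transfer may
    override it explicitly.
    """

    box: Box
    score: float
    stage: Stage = Stage.DETECTOR
    centroid: tuple[float, float] | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise InvalidGeometryError(f"score {self.score} outside [0, 1]")
        if self.centroid is None:
            object.__setattr__(self, "centroid", self.box.center)

    def with_stage(self, stage: Stage) -> "Detection":
        return replace(self, stage=stage)


@dataclass(frozen=True)
class DetectionLossInputs:
    """Inputs to the detection loss: predicted objectness ``p``, label
    ``p_star`` (1 = mitotic cell, 0 = background), predicted and
    ground-truth regression vectors, and the balance weight ``sigma``."""

    p: float
    p_star: int
    v: BoxRegressionVector
    v_star: BoxRegressionVector
    sigma: float = 1.0


def encode_box_regression(anchor: Box, proposal: Box) -> BoxRegressionVector:
    """Regression target carrying ``anchor`` onto ``proposal``.

    The translation components are normalized by the anchor size and the
    size components are natural-log ratios, so the target is invariant to
    a joint rescaling of both boxes.
    """
    xa, ya = anchor.center
    xp, yp = proposal.center
    return BoxRegressionVector(
        vx=(xp - xa) / anchor.width,
        vy=(yp - ya) / anchor.height,
        vw=math.log(proposal.width / anchor.width),
        vh=math.log(proposal.height / anchor.height),
    )


def decode_box_regression(anchor: Box, v: BoxRegressionVector) -> Box:
    """Exact inverse of :func:`encode_box_regression`."""
    xa, ya = anchor.center
    return Box.from_center(
        x=xa + v.vx * anchor.width,
        y=ya + v.vy * anchor.height,
        w=anchor.width * math.exp(v.vw),
        h=anchor.height * math.exp(v.vh),
    )


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(detections: Sequence[Detection], iou_threshold: float) -> list[Detection]:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-scoring remaining detection and discards
    every other detection whose IoU with it exceeds ``iou_threshold``.
    Equal scores are broken by input order, so the result is deterministic.
    Returns kept detections sorted by descending score.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ConfigError(f"NMS IoU threshold {iou_threshold} outside [0, 1]")
    # stable sort on negated score preserves input order among ties
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    kept: list[Detection] = []
    suppressed = [False] * len(detections)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(detections[i])
        for j in order:
            if j != i and not suppressed[j] and iou(detections[i].box, detections[j].box) > iou_threshold:
                suppressed[j] = True
    return kept


def generate_anchors(
    grid_shape: tuple[int, int],
    stride: float,
    scales: Sequence[float],
    ratios: Sequence[float],
) -> list[Box]:
    """Dense anchor boxes over a feature-map grid.

    One anchor per (cell, scale, ratio). Anchors are centered on grid-cell
    centers ``((col + 0.5) * stride, (row + 0.5) * stride)``. The ratio
    convention is area-preserving: for aspect ratio ``r = h/w`` the sides
    are ``w = scale / sqrt(r)``, ``h = scale * sqrt(r)``, so every anchor
    at a given scale has area ``scale**2``. Anchors may extend beyond the
    image; clipping is the caller's choice.
    """
    if not scales or not ratios:
        raise ConfigError("anchor scales and ratios must be non-empty")
    rows, cols = grid_shape
    anchors: list[Box] = []
    for row in range(rows):
        for col in range(cols):
            cx = (col + 0.5) * stride
            cy = (row + 0.5) * stride
            for scale in scales:
                for r in ratios:
                    w = scale / math.sqrt(r)
                    h = scale * math.sqrt(r)
                    anchors.append(Box.from_center(cx, cy, w, h))
    return anchors


def _smooth_l1(d: float) -> float:
    a = abs(d)
    return 0.5 * d * d if a < 1.0 else a - 0.5


def detection_loss(inputs: DetectionLossInputs) -> float:
    """Two-term detection loss ``L = Lcls + sigma * p* * Lreg``.

    ``Lcls`` is the binary cross-entropy of the objectness probability and
    ``Lreg`` the smooth-L1 distance between regression vectors, summed over
    the four components. The regression term is gated by the label, so it
    vanishes for background anchors.
    """
    if inputs.sigma < 0:
        raise ConfigError(f"negative sigma {inputs.sigma}")
    p = min(max(inputs.p, _EPS), 1.0 - _EPS)
    l_cls = -math.log(p) if inputs.p_star == 1 else -math.log(1.0 - p)
    l_reg = 0.0
    if inputs.p_star == 1:
        diff = inputs.v.as_array() - inputs.v_star.as_array()
        l_reg = float(sum(_smooth_l1(d) for d in diff))
    return l_cls + inputs.sigma * inputs.p_star * l_reg


def propose_and_filter(
    scores: Sequence[float],
    anchors: Sequence[Box],
    iou_threshold: float = 0.8,
) -> list[Detection]:
    """Pair per-anchor objectness scores with anchors and suppress overlaps.

    This is the proposal-filtering step applied to raw anchor scores before
    candidates are forwarded downstream; the default IoU threshold of 0.8
    matches the proposal-stage setting.
    """
    if len(scores) != len(anchors):
        raise InvalidGeometryError(
            f"{len(scores)} scores for {len(anchors)} anchors"
        )
    dets = [Detection(box=a, score=float(s)) for s, a in zip(scores, anchors)]
    return nms(dets, iou_threshold)


@dataclass(frozen=True)
class ReferenceDetectorConfig:
    """Configuration of the blob-based reference candidate detector.

    darkness_threshold
        Gray level (0-255) below which a pixel counts as candidate tissue.
    min_area / max_area
        Connected-component area band (px^2) kept as candidates.
    box_size
        Side length (px) of the fixed square box placed on each centroid.
    nms_threshold
        IoU threshold of the final suppression pass.
    reference_area
        Area (px^2) at which the size term of the score saturates.
    """

    darkness_threshold: float = 180.0
    min_area: int = 20
    max_area: int = 4000
    box_size: float = 48.0
    nms_threshold: float = 0.3
    reference_area: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 < self.darkness_threshold <= 255.0):
            raise ConfigError("darkness_threshold must be in (0, 255]")
        if self.min_area <= 0 or self.max_area < self.min_area:
            raise ConfigError("invalid candidate area band")


def _rgb_to_gray(image: np.ndarray) -> np.ndarray:
    # ITU-R 601 luma weights; the single gray convention used package-wide
    return image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114


def reference_detector(
    image: np.ndarray, config: ReferenceDetectorConfig | None = None
) -> list[Detection]:
    """Deterministic dark-blob candidate detector.

    Stands in for a trained region-proposal detector behind the same
    contract: it returns scored :class:`Detection` candidates. Pixels
    darker than ``darkness_threshold`` (ITU-R 601 gray) are grouped into
    connected components; components inside the area band become
    candidates boxed at ``box_size`` around their centroid. The score
    combines blob darkness and blob size (darker and larger blobs score
    higher, capped at 1), and overlapping candidates are suppressed by
    NMS. Output is a pure function of (image, config).
    """
    if config is None:
        config = ReferenceDetectorConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidGeometryError(f"expected HxWx3 RGB image, got shape {image.shape}")
    gray = _rgb_to_gray(image.astype(float))
    mask = gray < config.darkness_threshold
    labels, n_blobs = ndimage.label(mask)
    if n_blobs == 0:
        return []
    h, w = gray.shape
    dets: list[Detection] = []
    objects = ndimage.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        blob = labels[sl] == idx
        area = int(blob.sum())
        if not (config.min_area <= area <= config.max_area):
            continue
        ys, xs = np.nonzero(blob)
        cy = float(ys.mean()) + sl[0].start
        cx = float(xs.mean()) + sl[1].start
        mean_gray = float(gray[sl][blob].mean())
        darkness = 1.0 - mean_gray / 255.0
        size_term = min(1.0, area / config.reference_area)
        score = min(1.0, darkness * (0.5 + 0.5 * size_term))
        half = config.box_size / 2.0
        # clamp the box inside the image while keeping its size
        x0 = min(max(cx - half, 0.0), max(w - config.box_size, 0.0))
        y0 = min(max(cy - half, 0.0), max(h - config.box_size, 0.0))
        box = Box(x0, y0, min(x0 + config.box_size, w), min(y0 + config.box_size, h))
        dets.append(Detection(box=box, score=score, centroid=(cx, cy)))
    return nms(dets, config.nms_threshold)
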