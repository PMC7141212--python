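"""Dense patch extraction from large high-power-field images and
coordinate-consistent augmentation.

High-power fields are typically far larger (2084 x 2084 px at 40x) than
what a fixed-input detector or classifier consumes, so images are scanned
with a square window on a regular stride grid; annotations are re-expressed
in patch-local coordinates and patch-level detections can be mapped back to
the global frame. Augmentation (flips, translation, crop-resize) transforms
pixels and annotation coordinates together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .annotations import CentroidAnnotation
from .errors import ConfigError, InvalidGeometryError
from .geometry import Box, Detection

__all__ = [
    "PatchSpec",
    "AugmentOp",
    "AugmentRecord",
    "KeepRule",
    "extract_patches",
    "patch_to_global",
    "augment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatchSpec:
    """Location of a square patch inside a source image."""

    origin: tuple[int, int]  # (x, y) of the top-left pixel
    size: int
    source_image_id: str = ""


class KeepRule(str, Enum):
    ALL = "all"
    WITH_ANNOTATION = "with_annotation"


class AugmentOp(str, Enum):
    HFLIP = "hflip"
    VFLIP = "vflip"
    TRANSLATE = "translate"
    CROP_RESIZE = "crop_resize"


@dataclass(frozen=True)
class AugmentRecord:
    """One augmentation operation with its parameters and provenance.

    params:
      - translate: {"dx": int, "dy": int, "fill": optional RGB tuple}
        (fill defaults to the patch mean color)
      - crop_resize: {"x0": int, "y0": int, "w": int, "h": int}
        (window cropped then rescaled back to the original patch size)
      - hflip / vflip: no params
    """

    op: AugmentOp
    params: dict | None = None
    provenance: PatchSpec | None = None


def extract_patches(
    image: np.ndarray,
    annotations: Sequence[CentroidAnnotation],
    patch_size: int = 521,
    stride: int = 40,
    keep_rule: KeepRule = KeepRule.ALL,
    image_id: str = "",
) -> list[tuple[PatchSpec, np.ndarray, list[CentroidAnnotation]]]:
    """Densely extract square patches on a regular stride grid.

    Origins are ``(i * stride, j * stride)`` for every offset at which the
    whole patch fits inside the image; no boundary-clipped patches are
    produced. Each patch carries the annotations whose centroid falls
    inside it, re-expressed in patch-local coordinates. With
    ``keep_rule=WITH_ANNOTATION`` only patches containing at least one
    annotation are returned (the training-set construction rule).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if patch_size > h or patch_size > w:
        raise InvalidGeometryError(
            f"patch size {patch_size} exceeds image {w}x{h}"
        )
    if stride <= 0:
        raise ConfigError(f"stride must be positive, got {stride}")
    out = []
    for oy in range(0, h - patch_size + 1, stride):
        for ox in range(0, w - patch_size + 1, stride):
            local = [
                ann.shifted(-ox, -oy)
                for ann in annotations
                if ox <= ann.x < ox + patch_size and oy <= ann.y < oy + patch_size
            ]
            if keep_rule is KeepRule.WITH_ANNOTATION and not local:
                continue
            spec = PatchSpec(origin=(ox, oy), size=patch_size, source_image_id=image_id)
            out.append((spec, image[oy : oy + patch_size, ox : ox + patch_size], local))
    return out


def patch_to_global(
    spec: PatchSpec,
    detections: Sequence[Detection],
    image_shape: tuple[int, int] | None = None,
) -> list[Detection]:
    """Map patch-local detections to source-image coordinates.

    Boxes and centroids are offset by the patch origin; scores and stages
    are unchanged. If ``image_shape`` (height, width) is given, boxes that
    spill outside the source image are clipped with a warning.
    """
    ox, oy = spec.origin
    out: list[Detection] = []
    for det in detections:
        b = det.box
        x0, y0, x1, y1 = b.x_min + ox, b.y_min + oy, b.x_max + ox, b.y_max + oy
        if image_shape is not None:
            h, w = image_shape
            cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
            cx1, cy1 = min(x1, float(w)), min(y1, float(h))
            if (cx0, cy0, cx1, cy1) != (x0, y0, x1, y1):
                logger.warning(
                    "detection box (%s,%s,%s,%s) clipped to source image %sx%s",
                    x0, y0, x1, y1, w, h,
                )
                x0, y0, x1, y1 = cx0, cy0, cx1, cy1
        cx, cy = det.centroid
        out.append(
            replace(
                det,
                box=Box(x0, y0, x1, y1),
                centroid=(cx + ox, cy + oy),
            )
        )
    return out


def _check_rgb_or_gray(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.ndim not in (2, 3):
        raise InvalidGeometryError(f"expected 2-D or 3-D raster, got shape {patch.shape}")
    return patch


def augment(
    patch: np.ndarray,
    annotations: Sequence[CentroidAnnotation],
    record: AugmentRecord,
) -> tuple[np.ndarray, list[CentroidAnnotation]]:
    """Apply one augmentation to a patch and its annotations consistently.

    hflip maps column ``x -> W-1-x``; vflip maps row ``y -> H-1-y`` (both
    involutions). translate shifts pixels by (dx, dy) filling uncovered
    pixels with the patch mean color (configurable), dropping annotations
    pushed outside. crop_resize crops a window and rescales pixels and
    coordinates back to the original patch size.
    """
    patch = _check_rgb_or_gray(patch)
    h, w = patch.shape[:2]
    params = record.params or {}

    if record.op is AugmentOp.HFLIP:
        return patch[:, ::-1].copy(), [
            replace(a, x=w - 1 - a.x, region_pixels=None) for a in annotations
        ]
    if record.op is AugmentOp.VFLIP:
        return patch[::-1].copy(), [
            replace(a, y=h - 1 - a.y, region_pixels=None) for a in annotations
        ]
    if record.op is AugmentOp.TRANSLATE:
        dx, dy = int(params.get("dx", 0)), int(params.get("dy", 0))
        fill = params.get("fill")
        if fill is None:
            fill = patch.reshape(-1, patch.shape[2]).mean(axis=0) if patch.ndim == 3 else patch.mean()
        out = np.empty_like(patch)
        out[...] = np.round(fill).astype(patch.dtype) if np.issubdtype(patch.dtype, np.integer) else fill
        src_x0, src_x1 = max(0, -dx), min(w, w - dx)
        src_y0, src_y1 = max(0, -dy), min(h, h - dy)
        if src_x0 < src_x1 and src_y0 < src_y1:
            out[src_y0 + dy : src_y1 + dy, src_x0 + dx : src_x1 + dx] = patch[
                src_y0:src_y1, src_x0:src_x1
            ]
        kept = [
            a.shifted(dx, dy)
            for a in annotations
            if 0 <= a.x + dx < w and 0 <= a.y + dy < h
        ]
        return out, kept
    if record.op is AugmentOp.CROP_RESIZE:
        x0, y0 = int(params["x0"]), int(params["y0"])
        cw, ch = int(params["w"]), int(params["h"])
        if x0 < 0 or y0 < 0 or x0 + cw > w or y0 + ch > h or cw <= 0 or ch <= 0:
            raise InvalidGeometryError(
                f"crop window ({x0},{y0},{cw},{ch}) outside {w}x{h} patch"
            )
        window = patch[y0 : y0 + ch, x0 : x0 + cw]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resized = resize(
                window.astype(float), (h, w) + window.shape[2:], order=1,
                preserve_range=True, anti_aliasing=False,
            )
        if np.issubdtype(patch.dtype, np.integer):
            resized = np.clip(np.round(resized), 0, 255).astype(patch.dtype)
        sx, sy = w / cw, h / ch
        kept = [
            replace(a, x=(a.x - x0) * sx, y=(a.y - y0) * sy, region_pixels=None)
            for a in annotations
            if x0 <= a.x < x0 + cw and y0 <= a.y < y0 + ch
        ]
        return resized, kept
    raise ConfigError(f"unknown augmentation op {record.op!r}")
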