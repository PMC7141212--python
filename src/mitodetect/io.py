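"""Readers and writers for annotations, detections, calibration documents,
and the validated pipeline configuration.

All tabular interchange is CSV with mandatory headers; calibration
artifacts (filter cascade, fusion thresholds) and the pipeline
configuration are YAML. Configuration is validated strictly: unknown keys
are rejected and the schema version is checked.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pydantic
import yaml
from PIL import Image

from .annotations import CentroidAnnotation
from .errors import ConfigError, DataError
from .filtering import (
    Direction,
    FeatureFamily,
    FilterCascade,
    FilterStage,
    Scalarizer,
)
from .fusion import Combiner, FusionConfig
from .geometry import Box, Detection, Stage

__all__ = [
    "read_annotations",
    "write_detections",
    "read_detections",
    "save_cascade",
    "load_cascade",
    "save_fusion_config",
    "load_fusion_config",
    "load_dataset",
    "DetectorBlock",
    "TilingBlock",
    "FilterBlock",
    "FusionBlock",
    "EvaluationBlock",
    "PipelineConfig",
    "load_pipeline_config",
]

SCHEMA_VERSION = 1

DETECTION_HEADER = [
    "image_id", "x_min", "y_min", "x_max", "y_max",
    "centroid_x", "centroid_y", "score", "stage",
]


# ---------------------------------------------------------------- annotations

def read_annotations(
    path: str | Path,
    dialect: Literal["centroid_csv", "region_pixel_csv"] = "centroid_csv",
) -> list[CentroidAnnotation]:
    """Parse ground-truth annotations from CSV.

    ``centroid_csv`` rows are ``image_id,x,y[,class]``. In
    ``region_pixel_csv`` each row is ``image_id,mitosis_id,x,y`` listing
    the pixels of one annotated region; regions are reduced to their mean
    centroid rounded to the nearest integer. Parse errors name the
    offending line number. An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            rows.append([lineno, *row])
    if not rows:
        return []
    # optional header row
    if rows and not _is_number(rows[0][2]):
        rows = rows[1:]

    def parse_float(value: str, lineno: int) -> float:
        try:
            return float(value)
        except ValueError:
            raise DataError(f"{path}:{lineno}: not a number: {value!r}") from None

    if dialect == "centroid_csv":
        out = []
        for lineno, *row in rows:
            if len(row) < 3:
                raise DataError(f"{path}:{lineno}: expected image_id,x,y[,class]")
            out.append(
                CentroidAnnotation(
                    image_id=row[0],
                    x=parse_float(row[1], lineno),
                    y=parse_float(row[2], lineno),
                    class_label=row[3] if len(row) > 3 and row[3] else None,
                )
            )
        return out
    if dialect == "region_pixel_csv":
        groups: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for lineno, *row in rows:
            if len(row) < 4:
                raise DataError(f"{path}:{lineno}: expected image_id,mitosis_id,x,y")
            key = (row[0], row[1])
            groups.setdefault(key, []).append(
                (int(parse_float(row[2], lineno)), int(parse_float(row[3], lineno)))
            )
        out = []
        for (image_id, _), pixels in groups.items():
            xs = [p[0] for p in pixels]
            ys = [p[1] for p in pixels]
            out.append(
                CentroidAnnotation(
                    image_id=image_id,
                    x=float(round(sum(xs) / len(xs))),
                    y=float(round(sum(ys) / len(ys))),
                    region_pixels=tuple(pixels),
                )
            )
        return out
    raise ConfigError(f"unknown annotation dialect {dialect!r}")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ----------------------------------------------------------------- detections

def write_detections(path: str | Path, detections: Sequence[Detection]) -> None:
    """Write detections as CSV (coordinates exact, scores at 6 d.p.)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETECTION_HEADER)
        for d in detections:
            writer.writerow(
                [
                    d.image_id,
                    repr(d.box.x_min), repr(d.box.y_min),
                    repr(d.box.x_max), repr(d.box.y_max),
                    repr(d.centroid[0]), repr(d.centroid[1]),
                    f"{d.score:.6f}",
                    d.stage.value,
                ]
            )


def read_detections(path: str | Path) -> list[Detection]:
    """Read back a detections CSV written by :func:`write_detections`."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"detections file not found: {path}")
    out: list[Detection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != DETECTION_HEADER:
            raise DataError(f"{path}: unexpected header {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    Detection(
                        image_id=row["image_id"],
                        box=Box(
                            float(row["x_min"]), float(row["y_min"]),
                            float(row["x_max"]), float(row["y_max"]),
                        ),
                        centroid=(float(row["centroid_x"]), float(row["centroid_y"])),
                        score=float(row["score"]),
                        stage=Stage(row["stage"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
    return out


# ------------------------------------------------------- calibration documents

def save_cascade(path: str | Path, cascade: FilterCascade) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "stages": [
            {
                "feature_family": s.feature_family.value,
                "scalarizer": s.scalarizer.value,
                "threshold": float(s.threshold),
                "direction": s.direction.value,
                "component_index": s.component_index,
            }
            for s in cascade.stages
        ],
        "templates": {
            fam.value: [float(v) for v in vec]
            for fam, vec in cascade.templates.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_cascade(path: str | Path) -> FilterCascade:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    _check_schema(doc, path)
    stages = [
        FilterStage(
            feature_family=FeatureFamily(s["feature_family"]),
            scalarizer=Scalarizer(s["scalarizer"]),
            threshold=float(s["threshold"]),
            direction=Direction(s["direction"]),
            component_index=s.get("component_index"),
        )
        for s in doc["stages"]
    ]
    templates = {
        FeatureFamily(k): np.asarray(v, dtype=float)
        for k, v in doc.get("templates", {}).items()
    }
    return FilterCascade(stages=stages, templates=templates)


def save_fusion_config(path: str | Path, config: FusionConfig) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tau_a": config.tau_a,
        "tau_b": config.tau_b,
        "tau_fused": config.tau_fused,
        "weight_a": config.weight_a,
        "combiner": config.combiner.value,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_fusion_config(path: str | Path) -> FusionConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    _check_schema(doc, path)
    return FusionConfig(
        tau_a=float(doc["tau_a"]),
        tau_b=float(doc["tau_b"]),
        tau_fused=float(doc["tau_fused"]),
        weight_a=float(doc["weight_a"]),
        combiner=Combiner(doc.get("combiner", "mean")),
    )


def _check_schema(doc: object, path: str | Path) -> None:
    if not isinstance(doc, dict) or doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(f"{path}: missing or unsupported schema_version")


# -------------------------------------------------------------------- dataset

def load_dataset(
    data_dir: str | Path,
) -> list[tuple[str, np.ndarray, list[CentroidAnnotation]]]:
    """Load a generated dataset directory (manifest + PNGs + centroid CSVs)."""
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise DataError(f"no manifest.csv in {data_dir}")
    out = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(data_dir / row["image_file"]).convert("RGB"))
            annotations = read_annotations(data_dir / row["annotation_file"])
            out.append((row["image_id"], image, annotations))
    return out


# -------------------------------------------------------- pipeline config

class _StrictModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class DetectorBlock(_StrictModel):
    """Candidate-detector settings (anchors, suppression, blob detector)."""

    anchor_scales: list[float] = [64.0]
    anchor_ratios: list[float] = [0.5, 1.0, 2.0]
    proposal_iou_threshold: float = 0.8
    output_nms_threshold: float = 0.3
    darkness_threshold: float = 180.0
    min_area: int = 20
    max_area: int = 4000
    box_size: float = 48.0


class TilingBlock(_StrictModel):
    """Patch scan used when an image exceeds the detector's working size.

    ``scan_stride`` leaves one ``box_size``-scale overlap between
    neighboring windows so seam-straddling nuclei are still seen whole;
    duplicates are removed by the global NMS pass. The dense 40-px stride
    remains the default of the training-set extraction utility.
    """

    patch_size: int = 521
    scan_stride: int = 473
    dense_stride: int = 40


class FilterBlock(_StrictModel):
    recall_retention: float = 0.99
    objective: Literal["recall_retention", "max_f1"] = "recall_retention"
    stage_order: list[Literal["stats", "lbp", "hog", "color"]] = [
        "stats", "lbp", "hog", "color",
    ]


class FusionBlock(_StrictModel):
    objective: Literal["max_f1", "recall_retention"] = "max_f1"
    weight_a: float = 0.5
    combiner: Literal["mean", "product"] = "mean"


class EvaluationBlock(_StrictModel):
    criterion: Literal["icpr2012", "icpr2014"] = "icpr2012"


class PipelineConfig(_StrictModel):
    """Validated top-level configuration of the full pipeline."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    detector: DetectorBlock = DetectorBlock()
    tiling: TilingBlock = TilingBlock()
    filter: FilterBlock = FilterBlock()
    fusion: FusionBlock = FusionBlock()
    evaluation: EvaluationBlock = EvaluationBlock()


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a pipeline YAML config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if doc.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"{path}: unsupported schema_version")
    try:
        return PipelineConfig(**doc)
    except pydantic.ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from None
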