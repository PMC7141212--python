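"""Deterministic generator of histopathology-like test scenes and scores.

Real high-power fields are 2084 x 2084-pixel H&E tiles in which a handful
of mitotic figures — dark-bluish, irregular nuclei — hide among many
visually similar non-mitotic nuclei. The generator emulates exactly that
structure at configurable scale: a pink-ish background, anti-aliased
elliptical blobs of two classes with per-class color distributions and
speckle texture, and exact planted centroids as ground truth. A single
``margin`` knob scales the color separation between the classes, from
trivially separable (margin 1) toward fully overlapping (margin 0), which
is what the calibration-recovery tests dial.

A companion simulator draws correlated classifier-score pairs per class
for exercising the fusion stage in isolation. All outputs are bit-exact
reproducible from (config, seed).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .annotations import CentroidAnnotation
from .errors import ConfigError, DataError
from .fusion import ScorerOutput

__all__ = [
    "SceneConfig",
    "ScoreSimConfig",
    "generate_scene",
    "generate_dataset",
    "simulate_scores",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic high-power-field scene.

    Defaults emulate a full-size 2084 x 2084 HPF with a realistic mitotic
    burden (a few mitoses among many non-mitotic nuclei); tests and demos
    pass smaller ``image_size`` values with proportionally fewer blobs.
    ``margin`` in [0, 1] scales the non-mitotic class colors away from the
    mitotic ones: at 1 the classes are well separated, at 0 they coincide.
    """

    image_size: int = 2084
    n_mitotic: int = 4
    n_nonmitotic: int = 120
    mitotic_color_mean: tuple[float, float, float] = (62.0, 48.0, 118.0)
    mitotic_color_std: float = 8.0
    nonmitotic_color_mean: tuple[float, float, float] = (150.0, 120.0, 185.0)
    nonmitotic_color_std: float = 8.0
    radius_range: tuple[float, float] = (7.0, 14.0)
    texture_noise_sd: float = 6.0
    background_color: tuple[float, float, float] = (232.0, 205.0, 223.0)
    background_noise_sd: float = 3.0
    min_separation: float = 40.0
    margin: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigError("image_size too small")
        if not (0.0 <= self.margin <= 1.0):
            raise ConfigError("margin must be in [0, 1]")
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ConfigError("invalid radius_range")

    def effective_nonmitotic_mean(self) -> tuple[float, float, float]:
        m = np.asarray(self.mitotic_color_mean)
        n = np.asarray(self.nonmitotic_color_mean)
        return tuple(m + self.margin * (n - m))


@dataclass(frozen=True)
class ScoreSimConfig:
    """Bivariate-normal classifier-score simulation, one pair per candidate."""

    n_per_class: int = 1000
    positive_means: tuple[float, float] = (0.82, 0.78)
    negative_means: tuple[float, float] = (0.20, 0.26)
    sds: tuple[float, float] = (0.10, 0.10)
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.correlation <= 1.0):
            raise ConfigError("correlation outside [-1, 1]")
        if min(self.sds) < 0:
            raise ConfigError("negative score standard deviation")


def _place_centers(
    rng: np.random.Generator, config: SceneConfig, n: int, margin_px: float
) -> list[tuple[float, float]]:
    """Rejection-sample blob centers with pairwise minimum separation."""
    centers: list[tuple[float, float]] = []
    lo, hi = margin_px, config.image_size - margin_px
    if hi <= lo:
        raise ConfigError("blobs do not fit in the image")
    max_tries = 200 * max(n, 1)
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise ConfigError(
                f"could not place {n} blobs with separation {config.min_separation}"
            )
        x, y = rng.uniform(lo, hi, size=2)
        if all(
            (x - cx) ** 2 + (y - cy) ** 2 >= config.min_separation**2
            for cx, cy in centers
        ):
            centers.append((float(x), float(y)))
    return centers


def _render_blob(
    image: np.ndarray,
    rng: np.random.Generator,
    cx: float,
    cy: float,
    config: SceneConfig,
    color_mean: tuple[float, float, float],
    color_std: float,
) -> None:
    """Paint one anti-aliased textured ellipse in place."""
    r_lo, r_hi = config.radius_range
    a = rng.uniform(r_lo, r_hi)  # semi-axes
    b = rng.uniform(r_lo, r_hi)
    theta = rng.uniform(0.0, math.pi)
    color = np.clip(rng.normal(color_mean, color_std), 0, 255)

    r_max = max(a, b) + 2.0
    size = config.image_size
    x0, x1 = int(max(0, cx - r_max)), int(min(size, cx + r_max + 1))
    y0, y1 = int(max(0, cy - r_max)), int(min(size, cy + r_max + 1))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    # implicit radius; coverage ramps 1 -> 0 over ~1 px for anti-aliasing
    rr = np.sqrt(u**2 + v**2)
    edge = 1.0 / max(a, b)
    coverage = np.clip((1.0 + edge - rr) / (2.0 * edge), 0.0, 1.0)
    speckle = rng.normal(0.0, config.texture_noise_sd, size=rr.shape + (3,))
    blob_color = np.clip(color[None, None, :] + speckle, 0, 255)
    region = image[y0:y1, x0:x1]
    image[y0:y1, x0:x1] = (
        coverage[..., None] * blob_color + (1.0 - coverage[..., None]) * region
    )


def generate_scene(
    config: SceneConfig,
) -> tuple[np.ndarray, list[CentroidAnnotation]]:
    """Render one synthetic HPF and its exact planted annotations.

    Returns an 8-bit RGB image and one annotation per blob with
    ``class_label`` "mitotic" or "nonmitotic" at the planted centroid.
    Identical (config, seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    image = np.clip(
        np.asarray(config.background_color)[None, None, :]
        + rng.normal(0.0, config.background_noise_sd, size=(size, size, 3)),
        0,
        255,
    )
    n_total = config.n_mitotic + config.n_nonmitotic
    centers = _place_centers(
        rng, config, n_total, margin_px=config.radius_range[1] + 3.0
    )
    annotations: list[CentroidAnnotation] = []
    nonmitotic_mean = config.effective_nonmitotic_mean()
    for k, (cx, cy) in enumerate(centers):
        mitotic = k < config.n_mitotic
        _render_blob(
            image,
            rng,
            cx,
            cy,
            config,
            config.mitotic_color_mean if mitotic else nonmitotic_mean,
            config.mitotic_color_std if mitotic else config.nonmitotic_color_std,
        )
        annotations.append(
            CentroidAnnotation(
                image_id="",
                x=cx,
                y=cy,
                class_label="mitotic" if mitotic else "nonmitotic",
            )
        )
    return np.round(image).astype(np.uint8), annotations


def generate_dataset(
    config: SceneConfig,
    n_images: int,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Write ``n_images`` scenes as PNGs with centroid CSVs and a manifest.

    Image ``i`` uses seed ``base_seed + i`` (``base_seed`` defaults to the
    config seed), so the collection is deterministic. Returns the manifest
    path; the manifest lists image_id, file names, and per-class counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if seed is None else seed
    manifest_rows = []
    for i in range(n_images):
        image_id = f"img{i:03d}"
        cfg = replace(config, seed=base_seed + i)
        image, annotations = generate_scene(cfg)
        png = out / f"{image_id}.png"
        Image.fromarray(image).save(png)
        csv_path = out / f"{image_id}.csv"
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "x", "y", "class"])
            for ann in annotations:
                writer.writerow(
                    [image_id, f"{ann.x:.2f}", f"{ann.y:.2f}", ann.class_label]
                )
        manifest_rows.append(
            [image_id, png.name, csv_path.name, cfg.n_mitotic, cfg.n_nonmitotic]
        )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "image_file", "annotation_file", "n_mitotic", "n_nonmitotic"])
        writer.writerows(manifest_rows)
    return manifest


def simulate_scores(config: ScoreSimConfig) -> list[tuple[ScorerOutput, int]]:
    """Draw labeled classifier-score pairs from two bivariate normals.

    Positives (label 1) come first, then negatives; each class draws
    ``n_per_class`` pairs with the configured means, per-score standard
    deviations and correlation, clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed)
    sa, sb = config.sds
    cov = np.array(
        [[sa**2, config.correlation * sa * sb], [config.correlation * sa * sb, sb**2]]
    )
    out: list[tuple[ScorerOutput, int]] = []
    for means, label in ((config.positive_means, 1), (config.negative_means, 0)):
        draws = rng.multivariate_normal(means, cov, size=config.n_per_class)
        draws = np.clip(draws, 0.0, 1.0)
        out.extend(
            (ScorerOutput(float(a), float(b)), label) for a, b in draws
        )
    return out
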