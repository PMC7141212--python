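"""Shared fixtures: synthetic scenes, separated feature bundles, and a
calibrated pipeline reused by the end-to-end tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from mitodetect.features import FeatureBundle, FirstOrderStats

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mitodetect.io import PipelineConfig
from mitodetect.pipeline import PipelineCalibration, calibrate_pipeline
from mitodetect.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# scaled-down HPF used by the end-to-end tests: same structure as the
# full-size default, fewer pixels and blobs
EASY_SCENE = SceneConfig(
    image_size=512, n_mitotic=4, n_nonmitotic=20, margin=1.0, seed=100
)


def make_scenes(base_seed: int, n: int, prefix: str, config: SceneConfig = EASY_SCENE):
    out = []
    for i in range(n):
        image, anns = generate_scene(replace(config, seed=base_seed + i))
        out.append((f"{prefix}{i}", image, anns))
    return out


@pytest.fixture(scope="session")
def easy_train_scenes():
    return make_scenes(100, 5, "train")


@pytest.fixture(scope="session")
def easy_test_scenes():
    return make_scenes(200, 10, "test")


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def calibrated_pipeline(easy_train_scenes, pipeline_config) -> PipelineCalibration:
    return calibrate_pipeline(easy_train_scenes, pipeline_config)


def _normalized(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 1e-9, None)
    return v / v.sum()


def make_separated_bundles(
    rng: np.random.Generator, n: int, label: int, overlap: float = 0.0
) -> list[tuple[FeatureBundle, int]]:
    """Synthetic feature bundles with class separation in every family.

    ``overlap`` in [0, 1] pulls the two class distributions together;
    at 0 the classes are well separated relative to their spread.
    """
    shift = 1.0 - overlap
    if label == 1:
        stat_mean = np.array([50.0, 40.0, 0.5, 3.5])
        lbp_peak, color_peak, hog_dir = 40, 2, 0
    else:
        # direction of the stats vector changes, not just its magnitude,
        # so the cosine scalarization separates the classes too
        stat_mean = np.array([50.0 + 100.0 * shift, 40.0 - 35.0 * shift, 0.5, 3.5])
        lbp_peak, color_peak, hog_dir = 40 + int(120 * shift), 2 + int(9 * shift), 1
    out = []
    for _ in range(n):
        stats_vec = stat_mean + rng.normal(0, [3.0, 2.0, 0.2, 0.3])
        stats = FirstOrderStats(
            mean=float(stats_vec[0]), std=float(abs(stats_vec[1])),
            skewness=float(stats_vec[2]), kurtosis=float(abs(stats_vec[3])),
        )
        lbp = np.zeros(256)
        lbp[lbp_peak : lbp_peak + 40] = 1.0
        lbp = _normalized(lbp + rng.uniform(0, 0.2, 256))
        color = np.zeros(48)
        for c in range(3):
            color[16 * c + color_peak] = 1.0
        color = color + rng.uniform(0, 0.2, 48)
        color = np.concatenate([_normalized(color[16 * c : 16 * (c + 1)]) for c in range(3)])
        hog = rng.uniform(0, 0.05, 3780)
        hog[hog_dir::9] += 1.0
        out.append((FeatureBundle(stats=stats, lbp_hist=lbp, hog=hog, color_hist=color), label))
    return out
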