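"""Hierarchical score-level fusion of two candidate classifiers.

The final classification stage takes, for every surviving candidate, the
probability scores of two independent classifiers and passes them through
a three-stage threshold hierarchy: stage 1 thresholds the first score,
stage 2 the second, stage 3 the fused score; a candidate is declared
mitotic only if it clears every stage (strict ">" — ties reject). The
fused score is by default a weighted arithmetic mean (a product rule is
available). Thresholds are calibrated by grid search on labeled training
scores.

Any scorer meeting the :class:`ScorerOutput` contract plugs in; a logistic
scorer over handcrafted feature families is shipped as the reference (deep
convolutional scorers fit the same interface but are not part of this
package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, DataError, InvalidGeometryError
from .features import FeatureBundle

__all__ = [
    "ScorerOutput",
    "FusionConfig",
    "FusionObjective",
    "Combiner",
    "prepare_patch",
    "fuse_scores",
    "hierarchical_classify",
    "calibrate_fusion",
    "LogisticFeatureScorer",
]

PATCH_INPUT_SIZE = 224  # classifier input side length (px)
GRID_STEP = 0.01


@dataclass(frozen=True)
class ScorerOutput:
    """The probability pair produced by the two classifiers for one candidate."""

    score_a: float
    score_b: float

    def __post_init__(self) -> None:
        for name in ("score_a", "score_b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")


class Combiner(str, Enum):
    MEAN = "mean"  # weighted arithmetic mean (default)
    PRODUCT = "product"  # weighted geometric combination


class FusionObjective(str, Enum):
    MAX_F1 = "max_f1"
    RECALL_RETENTION = "recall_retention"


@dataclass(frozen=True)
class FusionConfig:
    """Per-stage thresholds and the fusion weight (weight_b = 1 - weight_a)."""

    tau_a: float = 0.5
    tau_b: float = 0.5
    tau_fused: float = 0.5
    weight_a: float = 0.5
    combiner: Combiner = Combiner.MEAN

    def __post_init__(self) -> None:
        for name in ("tau_a", "tau_b", "tau_fused", "weight_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")


def prepare_patch(patch: np.ndarray) -> np.ndarray:
    """Bilinear resize of an RGB candidate patch to the 224 x 224 classifier input."""
    patch = np.asarray(patch)
    if patch.size == 0:
        raise InvalidGeometryError("empty patch")
    target = (PATCH_INPUT_SIZE, PATCH_INPUT_SIZE) + patch.shape[2:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = resize(patch.astype(float), target, order=1, preserve_range=True,
                     anti_aliasing=False)
    if np.issubdtype(patch.dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(patch.dtype)
    return out


def fuse_scores(s: ScorerOutput, config: FusionConfig) -> float:
    """Fused probability of the two classifier scores.

    The default combiner is the weighted arithmetic mean
    ``weight_a * score_a + (1 - weight_a) * score_b``; the product rule
    uses the weighted geometric mean instead. Both stay within [0, 1] and
    return x for identical inputs (x, x).
    """
    wa = config.weight_a
    if config.combiner is Combiner.PRODUCT:
        return float(s.score_a**wa * s.score_b ** (1.0 - wa))
    return float(wa * s.score_a + (1.0 - wa) * s.score_b)


def hierarchical_classify(
    s: ScorerOutput, config: FusionConfig
) -> tuple[bool, int]:
    """Three-stage hierarchical decision.

    Stage 1 requires ``score_a > tau_a``, stage 2 ``score_b > tau_b``,
    stage 3 ``fused > tau_fused``; the candidate is mitotic iff all pass.
    Returns ``(is_mitotic, failing_stage)`` where ``failing_stage`` is the
    1-based first failing stage, or 0 on acceptance.
    """
    if s.score_a <= config.tau_a:
        return False, 1
    if s.score_b <= config.tau_b:
        return False, 2
    if fuse_scores(s, config) <= config.tau_fused:
        return False, 3
    return True, 0


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def calibrate_fusion(
    training: Sequence[tuple[ScorerOutput, int]],
    objective: FusionObjective = FusionObjective.MAX_F1,
    weight_a: float = 0.5,
    combiner: Combiner = Combiner.MEAN,
    recall_retention: float = 0.99,
) -> FusionConfig:
    """Grid-search the three thresholds on labeled training scores.

    All thresholds run over the grid 0.00, 0.01, ..., 1.00. With
    ``max_f1`` the F1 of the hierarchical decision is maximized; with
    ``recall_retention`` the search is restricted to configurations whose
    training recall is at least ``recall_retention`` and F1 is maximized
    within that set (falling back to max recall when the constraint is
    infeasible). Ties always break toward lower thresholds (tau_a, then
    tau_b, then tau_fused), so the result is deterministic and invariant
    to shuffling the training list.
    """
    labels = np.array([int(lab) for _, lab in training])
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == len(labels):
        raise DataError("fusion calibration needs both classes")
    sa = np.array([s.score_a for s, _ in training])
    sb = np.array([s.score_b for s, _ in training])
    base = FusionConfig(weight_a=weight_a, combiner=combiner)
    fused = np.array(
        [fuse_scores(ScorerOutput(a, b), base) for a, b in zip(sa, sb)]
    )
    grid = np.round(np.arange(0.0, 1.0 + GRID_STEP / 2, GRID_STEP), 2)

    best: tuple[float, float, float] | None = None
    best_value = -np.inf
    pos = labels == 1
    for ta in grid:
        mask_a = sa > ta
        for tb in grid:
            mask_ab = mask_a & (sb > tb)
            f_surv = fused[mask_ab]
            p_surv = pos[mask_ab]
            # sweep tau_fused in one vectorized pass over the grid
            order = np.argsort(f_surv, kind="stable")
            f_sorted = f_surv[order]
            cum_pos = np.concatenate([[0], np.cumsum(p_surv[order])])
            k = np.searchsorted(f_sorted, grid, side="right")
            tp = int(p_surv.sum()) - cum_pos[k]
            fp = (len(f_surv) - k) - tp
            fn = n_pos - tp
            recall = tp / n_pos
            denom = 2 * tp + fp + fn
            f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
            if objective is FusionObjective.RECALL_RETENTION:
                feasible = recall >= recall_retention
                # feasible configs (value in [1,2]) always beat infeasible ([0,1])
                value = np.where(feasible, 1.0 + f1, recall)
            else:
                value = f1
            i = int(np.argmax(value))  # first max -> lowest tau_fused
            if value[i] > best_value:  # strict -> lowest (tau_a, tau_b) wins ties
                best_value = float(value[i])
                best = (float(ta), float(tb), float(grid[i]))
    assert best is not None
    return FusionConfig(
        tau_a=best[0], tau_b=best[1], tau_fused=best[2],
        weight_a=weight_a, combiner=combiner,
    )


class LogisticFeatureScorer:
    """Reference candidate scorer: standardized logistic regression over a
    chosen subset of handcrafted feature families.

    Two instances over complementary families (for example statistics +
    color versus LBP + HOG) provide the two independent probability
    streams the fusion stage expects.
    """

    def __init__(self, families: Sequence[str] = ("stats", "color"), C: float = 1.0):
        self.families = tuple(families)
        self._scaler = StandardScaler()
        self._model = LogisticRegression(C=C, max_iter=1000)
        self._fitted = False

    def _design(self, bundles: Sequence[FeatureBundle]) -> np.ndarray:
        return np.array(
            [np.concatenate([b.family(f) for f in self.families]) for b in bundles]
        )

    def fit(self, training: Sequence[tuple[FeatureBundle, int]]) -> "LogisticFeatureScorer":
        labels = np.array([int(lab) for _, lab in training])
        if len(np.unique(labels)) < 2:
            raise DataError("scorer training needs both classes")
        x = self._scaler.fit_transform(self._design([b for b, _ in training]))
        self._model.fit(x, labels)
        self._fitted = True
        return self

    def score(self, bundles: Sequence[FeatureBundle]) -> np.ndarray:
        """Mitotic-class probability for each bundle, in [0, 1]."""
        if not self._fitted:
            raise DataError("scorer not fitted")
        if len(bundles) == 0:
            return np.empty(0)
        x = self._scaler.transform(self._design(bundles))
        return self._model.predict_proba(x)[:, 1]
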