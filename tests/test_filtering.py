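"""Per-feature threshold cascade: scalarization, calibration, application."""

import numpy as np
import pytest

from mitodetect.errors import CalibrationRequiredError, DataError
from mitodetect.features import FeatureBundle, FirstOrderStats
from mitodetect.filtering import (
    DEFAULT_STAGE_ORDER,
    Direction,
    FeatureFamily,
    FilterCascade,
    FilterStage,
    Scalarizer,
    apply_cascade,
    calibrate_cascade,
    scalar_score,
)
from mitodetect.geometry import Box, Detection, Stage

from conftest import make_separated_bundles


def bundle_from_vectors(stats=None, lbp=None, hog=None, color=None):
    stats = stats if stats is not None else np.array([10.0, 2.0, 0.1, 3.0])
    return FeatureBundle(
        stats=FirstOrderStats(*[float(v) for v in stats]),
        lbp_hist=lbp if lbp is not None else np.full(256, 1 / 256),
        hog=hog if hog is not None else np.zeros(3780),
        color_hist=color if color is not None else np.full(48, 1 / 48),
    )


def det(score=0.5):
    return Detection(box=Box(0, 0, 10, 10), score=score)


class TestScalarScore:
    def test_cosine_to_own_template_is_one(self):
        b = bundle_from_vectors(stats=[5.0, 1.0, 0.5, 2.0])
        stage = FilterStage(FeatureFamily.STATS, Scalarizer.COSINE_TO_TEMPLATE, 0.0)
        templates = {FeatureFamily.STATS: b.stats.as_array()}
        assert scalar_score(b, stage, templates) == pytest.approx(1.0)

    def test_identical_histograms_intersect_fully(self):
        h = np.zeros(256)
        h[[3, 77, 200]] = [0.5, 0.25, 0.25]
        b = bundle_from_vectors(lbp=h)
        stage = FilterStage(
            FeatureFamily.LBP, Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE, 0.0
        )
        assert scalar_score(b, stage, {FeatureFamily.LBP: h}) == pytest.approx(1.0)

    def test_disjoint_histograms_intersect_zero(self):
        h1, h2 = np.zeros(256), np.zeros(256)
        h1[:10] = 0.1
        h2[10:20] = 0.1
        b = bundle_from_vectors(lbp=h1)
        stage = FilterStage(
            FeatureFamily.LBP, Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE, 0.0
        )
        assert scalar_score(b, stage, {FeatureFamily.LBP: h2}) == 0.0

    def test_missing_template_raises(self):
        b = bundle_from_vectors()
        stage = FilterStage(FeatureFamily.HOG, Scalarizer.COSINE_TO_TEMPLATE, 0.0)
        with pytest.raises(CalibrationRequiredError):
            scalar_score(b, stage, {})


class TestCalibrate:
    def test_single_class_rejected(self, rng):
        training = make_separated_bundles(rng, 10, 1)
        with pytest.raises(DataError):
            calibrate_cascade(training)

    def test_full_retention_keeps_every_training_positive(self, rng):
        training = make_separated_bundles(rng, 40, 1) + make_separated_bundles(rng, 40, 0)
        cascade = calibrate_cascade(training, recall_retention=1.0)
        candidates = [(det(), b) for b, lab in training if lab == 1]
        accepted, _ = apply_cascade(candidates, cascade)
        assert len(accepted) == len(candidates)

    def test_separated_classes_fully_split_held_out(self, rng):
        train = make_separated_bundles(rng, 200, 1) + make_separated_bundles(rng, 200, 0)
        cascade = calibrate_cascade(train, recall_retention=0.99)
        held_pos = make_separated_bundles(rng, 200, 1)
        held_neg = make_separated_bundles(rng, 200, 0)
        acc_pos, _ = apply_cascade([(det(), b) for b, _ in held_pos], cascade)
        acc_neg, _ = apply_cascade([(det(), b) for b, _ in held_neg], cascade)
        assert len(acc_pos) == 200
        assert len(acc_neg) == 0

    def test_deterministic(self, rng):
        training = make_separated_bundles(rng, 30, 1) + make_separated_bundles(rng, 30, 0)
        c1 = calibrate_cascade(training)
        c2 = calibrate_cascade(training)
        assert [s.threshold for s in c1.stages] == [s.threshold for s in c2.stages]
        assert [s.direction for s in c1.stages] == [s.direction for s in c2.stages]


class TestApply:
    def test_empty_cascade_accepts_all(self, rng):
        cands = [(det(), b) for b, _ in make_separated_bundles(rng, 5, 0)]
        accepted, rejected = apply_cascade(cands, FilterCascade())
        assert len(accepted) == 5 and not rejected
        assert all(d.stage is Stage.FILTERED for d, _ in accepted)

    def test_rejection_tagged_with_first_failing_stage(self, rng):
        (b, _), = make_separated_bundles(rng, 1, 0)
        templates = {
            FeatureFamily.LBP: b.lbp_hist,
            FeatureFamily.COLOR: np.zeros(48),  # forces color-stage failure
        }
        stages = [
            FilterStage(FeatureFamily.COLOR, Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE, 0.5),
            FilterStage(FeatureFamily.LBP, Scalarizer.HISTOGRAM_INTERSECTION_TO_TEMPLATE, 0.5),
        ]
        cascade = FilterCascade(stages=stages, templates=templates)
        _, rejected = apply_cascade([(det(), b)], cascade)
        assert rejected[0][2] == 0  # short-circuits at stage 0

    def test_matches_bruteforce_predicate_oracle(self, rng):
        training = make_separated_bundles(rng, 50, 1) + make_separated_bundles(
            rng, 50, 0, overlap=0.8
        )
        cascade = calibrate_cascade(training, recall_retention=0.95)
        cands = [
            (det(), b)
            for b, _ in make_separated_bundles(rng, 50, 1, overlap=0.5)
            + make_separated_bundles(rng, 50, 0, overlap=0.5)
        ]
        accepted, rejected = apply_cascade(cands, cascade)
        # oracle: evaluate every stage predicate independently
        expected_accepted = []
        for d, b in cands:
            ok = all(
                s.accepts(scalar_score(b, s, cascade.templates)) for s in cascade.stages
            )
            if ok:
                expected_accepted.append(b)
        assert [b for _, b in accepted] == expected_accepted
        assert len(accepted) + len(rejected) == len(cands)

    def test_appending_stage_never_enlarges_accepted_set(self, rng):
        training = make_separated_bundles(rng, 60, 1, overlap=0.5) + make_separated_bundles(
            rng, 60, 0, overlap=0.5
        )
        cascade = calibrate_cascade(training, recall_retention=0.9)
        cands = [(det(), b) for b, _ in make_separated_bundles(rng, 80, 0, overlap=0.9)]
        prev: set[int] | None = None
        for k in range(len(cascade.stages) + 1):
            partial = FilterCascade(stages=cascade.stages[:k], templates=cascade.templates)
            accepted, _ = apply_cascade(cands, partial)
            ids = {id(b) for _, b in accepted}
            if prev is not None:
                assert ids <= prev
            prev = ids


def test_default_stage_order_covers_all_families():
    assert set(DEFAULT_STAGE_ORDER) == set(FeatureFamily)
    calibrated_direction = {Direction.ACCEPT_IF_GE, Direction.ACCEPT_IF_LE}
    assert calibrated_direction  # both directions representable
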