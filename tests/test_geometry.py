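"""Box geometry: regression encoding, IoU, NMS, anchors, loss, detector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodetect.errors import ConfigError, InvalidGeometryError
from mitodetect.geometry import (
    Box,
    BoxRegressionVector,
    Detection,
    DetectionLossInputs,
    ReferenceDetectorConfig,
    decode_box_regression,
    detection_loss,
    encode_box_regression,
    generate_anchors,
    iou,
    nms,
    propose_and_filter,
    reference_detector,
)

boxes = st.builds(
    Box.from_center,
    x=st.floats(-500, 500),
    y=st.floats(-500, 500),
    w=st.floats(0.5, 400),
    h=st.floats(0.5, 400),
)


def oracle_nms(detections, threshold):
    """Exhaustive suppression oracle: re-derives every keep/discard decision."""
    remaining = list(range(len(detections)))
    kept = []
    while remaining:
        best = min(remaining, key=lambda i: (-detections[i].score, i))
        kept.append(detections[best])
        remaining = [
            i
            for i in remaining
            if i != best and _oracle_iou(detections[best].box, detections[i].box) <= threshold
        ]
    return kept


def _oracle_iou(a, b):
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    area_a = (a.x_max - a.x_min) * (a.y_max - a.y_min)
    area_b = (b.x_max - b.x_min) * (b.y_max - b.y_min)
    return inter / (area_a + area_b - inter) if inter else 0.0


class TestBox:
    def test_degenerate_box_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Box(10, 0, 10, 5)
        with pytest.raises(InvalidGeometryError):
            Box.from_center(0, 0, -1, 5)

    def test_center_size_view(self):
        b = Box(10, 20, 50, 60)
        assert b.center == (30, 40)
        assert (b.width, b.height, b.area) == (40, 40, 1600)


class TestBoxRegression:
    def test_identity_encodes_to_zero(self):
        b = Box.from_center(10, 20, 30, 40)
        v = encode_box_regression(b, b)
        assert v == BoxRegressionVector(0, 0, 0, 0)

    def test_hand_computed_vector(self):
        anchor = Box.from_center(100, 100, 64, 64)
        proposal = Box.from_center(110, 92, 80, 48)
        v = encode_box_regression(anchor, proposal)
        assert v.vx == pytest.approx(0.15625)
        assert v.vy == pytest.approx(-0.125)
        assert v.vw == pytest.approx(0.223144, abs=1e-6)
        assert v.vh == pytest.approx(-0.287682, abs=1e-6)

    def test_width_doubling_is_log2(self):
        anchor = Box.from_center(0, 0, 10, 10)
        proposal = Box.from_center(0, 0, 20, 10)
        v = encode_box_regression(anchor, proposal)
        assert (v.vx, v.vy, v.vh) == (0, 0, 0)
        assert v.vw == pytest.approx(math.log(2))

    def test_zero_vector_decodes_to_anchor(self):
        anchor = Box.from_center(5, 7, 12, 9)
        assert decode_box_regression(anchor, BoxRegressionVector(0, 0, 0, 0)) == anchor

    def test_decode_matches_hand_example(self):
        anchor = Box.from_center(100, 100, 64, 64)
        v = BoxRegressionVector(0.15625, -0.125, math.log(1.25), math.log(0.75))
        out = decode_box_regression(anchor, v)
        assert out.center == pytest.approx((110, 92))
        assert (out.width, out.height) == pytest.approx((80, 48))

    def test_double_both_sides(self):
        anchor = Box.from_center(0, 0, 8, 6)
        out = decode_box_regression(anchor, BoxRegressionVector(0, 0, math.log(2), math.log(2)))
        assert out.center == pytest.approx((0, 0))
        assert (out.width, out.height) == pytest.approx((16, 12))

    def test_non_finite_vector_rejected(self):
        with pytest.raises(InvalidGeometryError):
            BoxRegressionVector(float("nan"), 0, 0, 0)

    @settings(max_examples=200, deadline=None)
    @given(anchor=boxes, proposal=boxes)
    def test_encode_decode_roundtrip(self, anchor, proposal):
        v = encode_box_regression(anchor, proposal)
        back = decode_box_regression(anchor, v)
        for got, want in zip(
            (back.x_min, back.y_min, back.x_max, back.y_max),
            (proposal.x_min, proposal.y_min, proposal.x_max, proposal.y_max),
        ):
            assert got == pytest.approx(want, rel=1e-9, abs=1e-6)
        v2 = encode_box_regression(anchor, back)
        assert np.allclose(v.as_array(), v2.as_array(), rtol=1e-9, atol=1e-9)


class TestIoU:
    def test_identical_and_disjoint(self):
        a = Box(0, 0, 10, 10)
        assert iou(a, a) == 1.0
        assert iou(a, Box(100, 100, 110, 110)) == 0.0

    def test_half_overlap_by_hand(self):
        assert iou(Box(0, 0, 10, 10), Box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    @settings(max_examples=200, deadline=None)
    @given(a=boxes, b=boxes)
    def test_symmetric_and_bounded(self, a, b):
        assert iou(a, b) == iou(b, a)
        assert 0.0 <= iou(a, b) <= 1.0


class TestNMS:
    def test_suppresses_heavy_overlap(self):
        a = Detection(box=Box(0, 0, 10, 10), score=0.9)
        b = Detection(box=Box(0, 0, 10, 10.5), score=0.8)
        kept = nms([a, b], 0.5)
        assert kept == [a]

    def test_disjoint_all_kept(self):
        dets = [
            Detection(box=Box(i * 20, 0, i * 20 + 10, 10), score=0.5 + 0.1 * i)
            for i in range(4)
        ]
        kept = nms(dets, 0.5)
        assert sorted(kept, key=lambda d: d.score) == dets

    def test_bad_threshold_rejected(self):
        with pytest.raises(ConfigError):
            nms([], 1.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 25))
        dets = [
            Detection(
                box=Box.from_center(*r.uniform(0, 100, 2), *r.uniform(5, 40, 2)),
                score=float(np.round(r.uniform(), 2)),  # rounded scores force ties
            )
            for _ in range(n)
        ]
        threshold = float(r.uniform(0.1, 0.9))
        assert nms(dets, threshold) == oracle_nms(dets, threshold)


class TestAnchors:
    def test_count(self):
        anchors = generate_anchors((2, 2), 16, [64], [0.5, 1.0, 2.0])
        assert len(anchors) == 12

    def test_unit_ratio_square(self):
        (a,) = generate_anchors((1, 1), 16, [64], [1.0])
        assert (a.width, a.height) == pytest.approx((64, 64))

    def test_area_preserving_ratio(self):
        (a,) = generate_anchors((1, 1), 16, [64], [2.0])
        assert a.height / a.width == pytest.approx(2.0)
        assert a.area == pytest.approx(64**2)
        assert a.width == pytest.approx(64 / math.sqrt(2))

    def test_empty_config_rejected(self):
        with pytest.raises(ConfigError):
            generate_anchors((1, 1), 16, [], [1.0])


class TestDetectionLoss:
    def _v(self, *vals):
        return BoxRegressionVector(*vals)

    def test_perfect_prediction_is_zero(self):
        loss = detection_loss(
            DetectionLossInputs(p=1.0, p_star=1, v=self._v(0, 0, 0, 0), v_star=self._v(0, 0, 0, 0))
        )
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_background_gates_regression(self):
        loss = detection_loss(
            DetectionLossInputs(p=0.3, p_star=0, v=self._v(5, 5, 5, 5), v_star=self._v(0, 0, 0, 0))
        )
        assert loss == pytest.approx(-math.log(0.7))

    def test_half_probability(self):
        loss = detection_loss(
            DetectionLossInputs(p=0.5, p_star=1, v=self._v(0, 0, 0, 0), v_star=self._v(0, 0, 0, 0))
        )
        assert loss == pytest.approx(0.693147, abs=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigError):
            detection_loss(
                DetectionLossInputs(
                    p=0.5, p_star=1, v=self._v(0, 0, 0, 0), v_star=self._v(0, 0, 0, 0), sigma=-1
                )
            )

    def test_nonnegative_and_decreasing_in_p(self):
        v = self._v(0.1, -0.2, 0.05, 0.0)
        losses = [
            detection_loss(DetectionLossInputs(p=p, p_star=1, v=v, v_star=v))
            for p in np.linspace(0.05, 0.95, 10)
        ]
        assert all(l >= 0 for l in losses)
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestProposeAndFilter:
    def test_single_anchor(self):
        (a,) = generate_anchors((1, 1), 16, [32], [1.0])
        out = propose_and_filter([0.7], [a])
        assert len(out) == 1 and out[0].score == 0.7

    def test_duplicate_anchor_keeps_best(self):
        (a,) = generate_anchors((1, 1), 16, [32], [1.0])
        out = propose_and_filter([0.7, 0.6], [a, a])
        assert len(out) == 1 and out[0].score == 0.7

    def test_length_mismatch(self):
        (a,) = generate_anchors((1, 1), 16, [32], [1.0])
        with pytest.raises(InvalidGeometryError):
            propose_and_filter([0.7, 0.6], [a])

    def test_matches_nms_oracle(self):
        r = np.random.default_rng(7)
        anchors = [
            Box.from_center(*r.uniform(0, 200, 2), *r.uniform(10, 60, 2))
            for _ in range(50)
        ]
        scores = np.round(r.uniform(size=50), 2)
        out = propose_and_filter(scores, anchors, iou_threshold=0.4)
        dets = [Detection(box=a, score=float(s)) for s, a in zip(scores, anchors)]
        assert out == oracle_nms(dets, 0.4)


class TestReferenceDetector:
    def test_blank_image_empty(self):
        image = np.full((64, 64, 3), 255, dtype=np.uint8)
        assert reference_detector(image) == []

    def test_finds_planted_blob(self):
        image = np.full((128, 128, 3), 240, dtype=np.uint8)
        yy, xx = np.mgrid[:128, :128]
        blob = (xx - 60) ** 2 + (yy - 70) ** 2 <= 8**2
        image[blob] = (60, 50, 120)
        dets = reference_detector(image)
        assert len(dets) >= 1
        cx, cy = dets[0].centroid
        assert math.hypot(cx - 60, cy - 70) < 5

    def test_deterministic(self):
        r = np.random.default_rng(3)
        image = r.integers(0, 255, size=(96, 96, 3), dtype=np.uint8)
        cfg = ReferenceDetectorConfig(min_area=5)
        assert reference_detector(image, cfg) == reference_detector(image, cfg)

    def test_non_rgb_rejected(self):
        with pytest.raises(InvalidGeometryError):
            reference_detector(np.zeros((64, 64)))
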