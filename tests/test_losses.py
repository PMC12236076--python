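"""Hand-derived oracle values and invariants of the IoU-family losses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phrfdet.losses import (FocalerParams, WIoUParams, WIoUState,
                            detection_box_objective, focaler_iou,
                            focaler_wiou_v3_loss, giou_loss, iou,
                            pairwise_giou, pairwise_iou, wiou_v1_loss,
                            wiou_v3_loss, cxcywh_to_xyxy, xyxy_to_cxcywh)
from phrfdet.nn import Tensor

P = [0.0, 0.0, 2.0, 2.0]
G = [1.0, 1.0, 3.0, 3.0]


class TestIoU:
    def test_identical_boxes(self):
        assert iou(G, G) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou([0, 0, 1, 1], [5, 5, 6, 6]) == 0.0

    def test_hand_value(self):
        assert iou(P, G) == pytest.approx(1 / 7, abs=1e-6)

    def test_zero_union_convention(self):
        assert iou([0, 0, 0, 0], [0, 0, 0, 0]) == 0.0


class TestGIoU:
    def test_identical_boxes_zero_loss(self):
        assert giou_loss(G, G) == pytest.approx(0.0, abs=1e-6)

    def test_hand_value(self):
        # enclosing area 9, union 7: GIoU = 1/7 - 2/9
        assert giou_loss(P, G) == pytest.approx(1 - (1 / 7 - 2 / 9), abs=1e-6)

    def test_far_separation_approaches_two(self):
        a = [0.0, 0.0, 1.0, 1.0]
        prev = 0.0
        for d in (10, 100, 1000):
            val = giou_loss(a, [d, 0, d + 1, 1])
            assert val > prev
            prev = val
        assert prev > 1.99

    def test_degenerates_to_iou_at_complete_overlap(self):
        assert 1 - giou_loss(G, G) == pytest.approx(iou(G, G), abs=1e-6)


class TestWIoUv1:
    def test_identical_boxes(self):
        assert wiou_v1_loss(G, G) == pytest.approx(0.0, abs=1e-6)

    def test_hand_value(self):
        # centers (1,1),(2,2): d^2 = 2; enclosing 3x3: denominator 18
        expected = np.exp(2 / 18) * (6 / 7)
        assert wiou_v1_loss(P, G) == pytest.approx(expected, abs=1e-6)

    def test_distance_factor_at_least_one(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 4)).reshape(4)
            b = np.sort(rng.uniform(0, 10, 4)).reshape(4)
            a = [a[0], a[1], a[2], a[3]]
            b = [b[0], b[1], b[2], b[3]]
            liou = 1 - iou(a, b)
            assert wiou_v1_loss(a, b) >= liou - 1e-6


class TestWIoUv3:
    def test_focusing_coefficient_formula(self):
        # beta=1 (warm-up), alpha=1.9, delta=3: r = 1.9^2 / 3
        state = WIoUState()
        expected_r = 1.9**2 / 3
        v1 = wiou_v1_loss(P, G)
        v3 = wiou_v3_loss(P, G, state, WIoUParams())
        assert v3 == pytest.approx(expected_r * v1, abs=1e-5)

    def test_beta_equals_delta_reduces_to_v1(self):
        params = WIoUParams(alpha=1.9, delta=3.0, momentum=1.0)
        liou = 1 - iou(P, G)
        state = WIoUState(running_mean=liou / 3.0, initialized=True)  # beta = 3 = delta
        v3 = wiou_v3_loss(P, G, state, params, update_state=False)
        assert v3 == pytest.approx(wiou_v1_loss(P, G), abs=1e-5)

    def test_identical_boxes_zero(self):
        assert wiou_v3_loss(G, G, WIoUState()) == pytest.approx(0.0, abs=1e-6)

    def test_state_updates_by_ema(self):
        state = WIoUState()
        params = WIoUParams(momentum=0.5)
        wiou_v3_loss(P, G, state, params)
        first = state.running_mean
        assert first == pytest.approx(6 / 7, abs=1e-5)
        wiou_v3_loss(G, G, state, params)  # perfect pair, L_IoU = 0
        assert state.running_mean == pytest.approx(0.5 * first, abs=1e-5)


class TestFocalerIoU:
    def test_lower_boundary(self):
        assert focaler_iou(0.0, FocalerParams(0.0, 0.95)) == 0.0

    def test_upper_branch(self):
        assert focaler_iou(0.97, FocalerParams(0.0, 0.95)) == 1.0

    def test_hand_value(self):
        assert focaler_iou(0.5, FocalerParams(0.0, 0.95)) == pytest.approx(
            0.5 / 0.95, abs=1e-6
        )

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            FocalerParams(0.9, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, a, b):
        params = FocalerParams(0.2, 0.8)
        fa, fb = focaler_iou(a, params), focaler_iou(b, params)
        assert 0.0 <= fa <= 1.0
        if a <= b:
            assert fa <= fb

    def test_continuity_and_boundary_values(self):
        params = FocalerParams(0.3, 0.7)
        assert focaler_iou(0.3, params) == pytest.approx(0.0, abs=1e-6)
        assert focaler_iou(0.7, params) == pytest.approx(1.0, abs=1e-6)
        grid = np.linspace(0, 1, 1001)
        vals = focaler_iou(grid, params)
        assert np.abs(np.diff(vals)).max() < 0.005  # no jumps


class TestFocalerWIoUv3:
    def test_identical_boxes_zero(self):
        assert focaler_wiou_v3_loss(G, G, WIoUState()) == pytest.approx(0.0, abs=1e-6)

    def test_identity_interval_reduces_to_wiou_v3_exactly(self):
        la = focaler_wiou_v3_loss(P, G, WIoUState(),
                                  fparams=FocalerParams(0.0, 1.0))
        lb = wiou_v3_loss(P, G, WIoUState())
        assert la == lb  # the +IoU - IoU_focaler correction cancels exactly

    def test_composition_hand_value(self):
        # r forced to 1 via beta = delta
        params = WIoUParams(alpha=1.9, delta=3.0)
        liou = 6 / 7
        state = WIoUState(running_mean=liou / 3.0, initialized=True)
        val = focaler_wiou_v3_loss(P, G, state, params,
                                   FocalerParams(0.0, 0.95),
                                   update_state=False)
        expected = np.exp(2 / 18) * (6 / 7) + 1 / 7 - (1 / 7) / 0.95
        assert val == pytest.approx(expected, abs=1e-5)

    @given(st.lists(st.floats(0, 10), min_size=8, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_always_finite_even_for_degenerate_boxes(self, vals):
        a = [min(vals[0], vals[2]), min(vals[1], vals[3]),
             max(vals[0], vals[2]), max(vals[1], vals[3])]
        b = [min(vals[4], vals[6]), min(vals[5], vals[7]),
             max(vals[4], vals[6]), max(vals[5], vals[7])]
        for fn in (iou, giou_loss, wiou_v1_loss):
            assert np.isfinite(fn(a, b))
        assert np.isfinite(focaler_wiou_v3_loss(a, b, WIoUState()))


class TestDetectionObjective:
    def test_perfect_matches_zero_box_term(self):
        pred = np.array([G, [4, 4, 5, 5]], dtype=np.float32)
        out = detection_box_objective(pred, pred, WIoUState())
        assert out.item() == pytest.approx(0.0, abs=1e-6)

    def test_empty_match_set(self):
        out = detection_box_objective(np.zeros((0, 4)), np.zeros((0, 4)),
                                      WIoUState())
        assert out.item() == 0.0

    def test_single_pair_reduction_identity(self):
        pred = np.array([P], dtype=np.float32)
        gt = np.array([G], dtype=np.float32)
        state_a, state_b = WIoUState(), WIoUState()
        full = detection_box_objective(pred, gt, state_a, weight_l1=0.0,
                                       weight_iou=1.0)
        single = focaler_wiou_v3_loss(P, G, state_b)
        assert full.item() == pytest.approx(single, abs=1e-5)

    @pytest.mark.parametrize("gt_box", [
        [0.5, 0.5, 2.5, 2.5],   # overlapping
        [2.0, 0.0, 4.0, 2.0],   # touching
        [5.0, 5.0, 7.0, 7.0],   # disjoint
    ])
    def test_gradients_finite_for_all_geometries(self, gt_box):
        pred = Tensor(np.array([P], dtype=np.float32), requires_grad=True)
        loss = detection_box_objective(
            pred, Tensor(np.array([gt_box], dtype=np.float32)), WIoUState()
        )
        loss.backward()
        assert np.isfinite(pred.grad).all()


def test_monotone_loss_decrease_for_nested_translations():
    """Sliding a box toward its target decreases L_IoU and GIoU loss."""
    gt = [0.0, 0.0, 2.0, 2.0]
    prev_liou, prev_giou = np.inf, np.inf
    for shift in (3.0, 2.0, 1.0, 0.5, 0.0):
        b = [shift, 0.0, shift + 2.0, 2.0]
        liou = 1 - iou(b, gt)
        gl = giou_loss(b, gt)
        assert liou <= prev_liou + 1e-9 and gl <= prev_giou + 1e-9
        prev_liou, prev_giou = liou, gl


def test_box_format_conversions_roundtrip(rng):
    b = rng.uniform(0, 1, (10, 4)).astype(np.float32)
    b[:, 2:] = b[:, :2] + np.abs(b[:, 2:])  # valid corners
    np.testing.assert_allclose(cxcywh_to_xyxy(xyxy_to_cxcywh(b)), b, atol=1e-6)


def test_pairwise_matches_elementwise(rng):
    a = np.sort(rng.uniform(0, 5, (6, 4)), axis=-1)
    b = np.sort(rng.uniform(0, 5, (4, 4)), axis=-1)
    m = pairwise_iou(a, b)
    g = pairwise_giou(a, b)
    for i in range(6):
        for j in range(4):
            assert m[i, j] == pytest.approx(iou(list(a[i]), list(b[j])), abs=1e-5)
            assert 1 - g[i, j] == pytest.approx(
                giou_loss(list(a[i]), list(b[j])), abs=1e-5
            )
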