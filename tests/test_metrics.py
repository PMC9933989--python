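"""Metric implementations against independent loop-based oracles."""

import numpy as np
import pytest

from glottikit.metrics import (
    EvalReport,
    iou,
    mape,
    mape_per_image,
    summarize,
    trajectory_jitter,
)


def mape_oracle(pred, true, one_based=True):
    """Per-coordinate loop evaluation of the percentage-error mean."""
    shift = 1.0 if one_based else 0.0
    scores = []
    for (pa, pp_), (ta, tp) in zip(pred, true):
        coords_p = [pa[0], pa[1], pp_[0], pp_[1]]
        coords_t = [ta[0], ta[1], tp[0], tp[1]]
        s = 0.0
        for yp, yt in zip(coords_p, coords_t):
            s += abs((yp + shift) - (yt + shift)) / abs(yt + shift)
        scores.append(100.0 * s / 4.0)
    return scores


class TestMape:
    def test_perfect_prediction(self):
        pts = np.array([[[3.0, 4.0], [5.0, 9.0]]])
        assert mape(pts, pts) == 0.0

    def test_ten_percent_offset(self):
        true = np.array([[[99.0, 99.0], [99.0, 99.0]]])  # 100 one-based
        pred = np.array([[[109.0, 109.0], [109.0, 109.0]]])
        assert mape(pred, true) == pytest.approx(10.0)

    def test_matches_loop_oracle(self, rng):
        pred = rng.uniform(1, 50, size=(25, 2, 2))
        true = rng.uniform(1, 50, size=(25, 2, 2))
        got = mape_per_image(pred, true)
        np.testing.assert_allclose(got, mape_oracle(pred, true), atol=1e-9)

    def test_scale_invariance(self, rng):
        pred = rng.uniform(5, 50, size=(10, 2, 2))
        true = rng.uniform(5, 50, size=(10, 2, 2))
        a = mape_per_image(pred, true, one_based=False)
        b = mape_per_image(3.0 * pred, 3.0 * true, one_based=False)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            mape(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))

    def test_zero_true_coordinate_guard(self):
        pts = np.array([[[0.0, 5.0], [3.0, 4.0]]])
        assert np.isfinite(mape(pts, pts))  # one-based shift avoids 0/0
        with pytest.raises(ValueError):
            mape(pts, pts, one_based=False)


class TestIoU:
    def test_identical_nonempty(self):
        m = np.zeros((9, 9))
        m[2:5, 2:5] = 1
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((9, 9))
        b = np.zeros((9, 9))
        a[0, 0] = 1
        b[5, 5] = 1
        assert iou(a, b) == 0.0

    def test_nested_half(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[0, :4] = 1       # 4 px
        b[0, :4] = 1
        b[1, :4] = 1       # 8 px superset
        assert iou(a, b) == 0.5

    def test_both_empty_convention(self):
        assert iou(np.zeros((5, 5)), np.zeros((5, 5))) == 1.0

    def test_symmetry(self, rng):
        a = rng.uniform(size=(12, 12)) > 0.6
        b = rng.uniform(size=(12, 12)) > 0.6
        assert iou(a, b) == iou(b, a)

    def test_counting_oracle(self, rng):
        a = rng.uniform(size=(8, 8)) > 0.5
        b = rng.uniform(size=(8, 8)) > 0.5
        inter = union = 0
        for x, y in zip(a.ravel(), b.ravel()):
            inter += int(x and y)
            union += int(x or y)
        assert iou(a, b) == pytest.approx(inter / union, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((3, 3)), np.zeros((4, 4)))


class TestJitter:
    def test_perfect_constant_prediction(self):
        true = np.array([[2.0, 3.0], [4.0, 9.0]])
        traj = np.tile(true[None], (8, 1, 1))
        out = trajectory_jitter(traj, true)
        assert out == {"ap_std": 0.0, "pp_std": 0.0}

    def test_alternating_distances(self):
        true = np.array([[0.0, 0.0], [10.0, 10.0]])
        traj = np.tile(true[None], (6, 1, 1))
        traj[1::2, 0, 0] += 2.0  # ap distance alternates 0, 2
        assert trajectory_jitter(traj, true)["ap_std"] == pytest.approx(1.0)

    def test_two_pass_oracle(self, rng):
        true = rng.uniform(0, 20, size=(2, 2))
        traj = true[None] + rng.normal(size=(15, 2, 2))
        got = trajectory_jitter(traj, true)
        for idx, key in ((0, "ap_std"), (1, "pp_std")):
            d = [float(np.hypot(*(traj[t, idx] - true[idx])))
                 for t in range(15)]
            mean = sum(d) / len(d)
            var = sum((x - mean) ** 2 for x in d) / len(d)
            assert got[key] == pytest.approx(np.sqrt(var), abs=1e-9)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            trajectory_jitter(np.zeros((1, 2, 2)), np.zeros((2, 2)))


class TestSummarize:
    def test_single_score(self):
        s = summarize([4.2])
        assert set(s.values()) == {4.2}

    def test_interpolated_median(self):
        assert summarize([1, 2, 3, 4])["median"] == 2.5
        assert summarize([1, 2, 3, 4])["q1"] == 1.75

    def test_order_property(self, rng):
        s = summarize(rng.uniform(size=50))
        assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


def test_eval_report_round_trip():
    rep = EvalReport(
        mape_summary={"median": 2.0, "q1": 1.0, "q3": 3.0,
                      "min": 0.5, "max": 9.0},
        mean_iou=0.86,
        jitter={"v0": {"ap_std": 0.4, "pp_std": 0.2}})
    again = EvalReport.from_json(rep.to_json())
    assert again == rep


def test_eval_report_rejects_disordered_summary():
    with pytest.raises(ValueError):
        EvalReport(mape_summary={"median": 1.0, "q1": 2.0, "q3": 3.0,
                                 "min": 0.0, "max": 4.0},
                   mean_iou=0.5, jitter={})
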