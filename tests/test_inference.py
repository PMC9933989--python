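"""Keypoint decoding, midline assembly, and the moving median filter."""

import numpy as np
import pytest

from glottikit.inference import (
    DegenerateMapError,
    decode_keypoints,
    decode_map,
    midline_from_points,
    moving_median_filter,
    predict_video,
)
from glottikit.preprocessing import make_target_map


def median_filter_oracle(series, window):
    """Independent pad-sort-select evaluation on one 1-D series."""
    series = list(series)
    lead = -(-(window - 1) // 2)  # ceil
    trail = (window - 1) // 2
    padded = [series[0]] * lead + series + [series[-1]] * trail
    out = []
    for i in range(len(series)):
        win = sorted(padded[i:i + window])
        mid = window // 2
        if window % 2:
            out.append(win[mid])
        else:
            out.append(0.5 * (win[mid - 1] + win[mid]))
    return out


class TestDecode:
    def test_ideal_disk_center_recovered(self):
        disk = make_target_map((10, 10), (24, 24), 2)
        assert decode_map(disk) == pytest.approx((10.0, 10.0))

    def test_single_pixel(self):
        m = np.zeros((12, 12))
        m[7, 3] = 0.4
        assert decode_map(m) == pytest.approx((3.0, 7.0))

    def test_ambiguous_map_returns_centroid(self):
        m = np.zeros((8, 8))
        m[0, 0] = m[0, 4] = 1.0
        assert decode_map(m) == (2.0, 0.0)

    def test_argmax_option(self):
        m = np.zeros((8, 8))
        m[5, 2] = 1.0
        m[1, 1] = 0.9
        assert decode_map(m, method="argmax") == (2.0, 5.0)

    def test_zero_channel_named(self):
        maps = np.zeros((10, 10, 2))
        maps[..., 0] = make_target_map((4, 4), (10, 10), 2)
        with pytest.raises(DegenerateMapError, match="posterior"):
            decode_keypoints(maps)

    def test_decode_inverts_encode(self, rng):
        for radius in (5, 8, 10, 12, 15, 20):
            for _ in range(5):
                p = tuple(rng.uniform(radius + 1, 63 - radius - 1, size=2))
                maps = np.stack([
                    make_target_map(p, (64, 64), radius),
                    make_target_map(p, (64, 64), radius)], axis=-1)
                ap, pp = decode_keypoints(maps)
                assert ap == pytest.approx(p, abs=0.5)
                assert pp == pytest.approx(p, abs=0.5)


class TestMidline:
    def test_vertical_line(self):
        m = midline_from_points((0, 0), (0, 10))
        assert m.direction == pytest.approx((0.0, -1.0))

    def test_three_four_five(self):
        m = midline_from_points((3, 4), (0, 0))
        assert m.direction == pytest.approx((0.6, 0.8))

    def test_antisymmetric(self):
        a = midline_from_points((3, 4), (1, 1)).direction
        b = midline_from_points((1, 1), (3, 4)).direction
        assert a == pytest.approx((-b[0], -b[1]))

    def test_coincident_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            midline_from_points((2, 2), (2, 2))


class TestMovingMedian:
    def test_constant_unchanged(self):
        traj = np.tile(np.array([[[3.0, 4.0], [5.0, 6.0]]]), (9, 1, 1))
        for w in (1, 2, 5, 12):
            np.testing.assert_array_equal(moving_median_filter(traj, w), traj)

    def test_window_one_identity(self, rng):
        traj = rng.normal(size=(7, 2, 2))
        np.testing.assert_array_equal(moving_median_filter(traj, 1), traj)

    def test_spike_removed(self):
        traj = np.zeros((3, 2, 2))
        traj[1, 0, 0] = 10.0
        out = moving_median_filter(traj, 3)
        np.testing.assert_array_equal(out[:, 0, 0], [0.0, 0.0, 0.0])

    @pytest.mark.parametrize("window", range(1, 19))
    def test_matches_pad_sort_select_oracle(self, window, rng):
        for _ in range(5):
            t = int(rng.integers(2, 40))
            traj = rng.normal(size=(t, 2, 2))
            got = moving_median_filter(traj, window)
            assert got.shape == traj.shape
            for i in range(2):
                for j in range(2):
                    np.testing.assert_allclose(
                        got[:, i, j],
                        median_filter_oracle(traj[:, i, j], window),
                        atol=1e-12)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            moving_median_filter(np.zeros((5, 2, 2)), 0)

    def test_oversized_window_warns(self):
        with pytest.warns(UserWarning, match="padding"):
            moving_median_filter(np.zeros((3, 2, 2)), 30)


@pytest.fixture(scope="module")
def model():
    from glottikit.architectures import ModelConfig, build_model
    return build_model(ModelConfig(variant="v2e", base_filters=8,
                                   input_size=(32, 16), seed=0))


class TestPredictVideo:
    def test_trajectory_length_preserved(self, model, rng):
        frames = rng.uniform(-1, 1, size=(30, 32, 16)).astype(np.float32)
        traj, seg = predict_video(model, frames)
        assert traj.shape == (30, 2, 2)
        assert seg.shape == (30, 32, 16)
        traj_f, _ = predict_video(model, frames, window=12)
        assert traj_f.shape == (30, 2, 2)

    def test_window_one_equals_unfiltered(self, model, rng):
        frames = rng.uniform(-1, 1, size=(6, 32, 16)).astype(np.float32)
        t1, _ = predict_video(model, frames, window=1)
        t0, _ = predict_video(model, frames)
        np.testing.assert_array_equal(t0, t1)

    def test_channels_mode_sliding_window(self, rng):
        from glottikit.architectures import ModelConfig, build_temporal_model
        cfg = ModelConfig(variant="v2e", temporal_mode="channels",
                          base_filters=8, n_frames=3, input_size=(32, 16))
        model = build_temporal_model(cfg)
        frames = rng.uniform(-1, 1, size=(7, 32, 16)).astype(np.float32)
        traj, seg = predict_video(model, frames)
        assert traj.shape == (7, 2, 2)
        assert seg.shape == (7, 32, 16)


def test_filtering_reduces_noise_std(rng):
    """Median smoothing shrinks the spread of a noisy constant trajectory."""
    from glottikit.metrics import trajectory_jitter
    true = np.array([[10.0, 5.0], [11.0, 25.0]])
    noisy = true[None] + rng.normal(0, 3.0, size=(30, 2, 2))
    raw = trajectory_jitter(noisy, true)
    filt = trajectory_jitter(moving_median_filter(noisy, 12), true)
    assert filt["ap_std"] < raw["ap_std"]
    assert filt["pp_std"] < raw["pp_std"]
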