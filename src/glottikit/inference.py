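"""Keypoint decoding, midline assembly, and temporal trajectory filtering.

The network emits one localization map per keypoint.  Decoding thresholds a
map at half its maximum and returns the intensity-weighted centroid of the
supra-threshold pixels, which recovers the center of an ideal disk exactly
and is robust to plateaued maxima; row-major argmax is available as an
alternative.  Per-video point trajectories can be smoothed with a moving
median filter whose window of 12-18 frames (about one oscillation cycle)
suppresses frame-to-frame jitter without shortening the video.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "Midline",
    "PointTrajectory",
    "decode_keypoints",
    "decode_map",
    "midline_from_points",
    "moving_median_filter",
    "predict_video",
    "DegenerateMapError",
]


class DegenerateMapError(ValueError):
    """A localization map contains no positive evidence to decode."""


@dataclass(frozen=True)
class Midline:
    """The glottal midline anchored at the anterior and posterior points."""

    ap: tuple[float, float]
    pp: tuple[float, float]
    direction: tuple[float, float]  # unit vector from pp towards ap


PointTrajectory = np.ndarray
"""Per-frame (ap, pp) points: array of shape (T, 2, 2), last axis (x, y)."""


def decode_map(channel: np.ndarray, method: str = "centroid"
               ) -> tuple[float, float]:
    """Decode one localization map to an (x, y) point."""
    m = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("localization map contains non-finite values")
    peak = m.max()
    if peak <= 0:
        raise DegenerateMapError("all-zero localization map")
    if method == "argmax":
        idx = np.unravel_index(np.argmax(m), m.shape)
        return (float(idx[1]), float(idx[0]))
    if method != "centroid":
        raise ValueError(f"unknown decode method {method!r}")
    mask = m >= 0.5 * peak
    weights = m[mask]
    rr, cc = np.nonzero(mask)
    total = weights.sum()
    return (float((cc * weights).sum() / total),
            float((rr * weights).sum() / total))


def decode_keypoints(pred_maps: np.ndarray, method: str = "centroid"
                     ) -> tuple[tuple[float, float], tuple[float, float]]:
    """(H, W, 2) prediction maps -> (ap, pp) points.

    Channel 0 is the anterior point, channel 1 the posterior point.  An
    all-zero channel raises :class:`DegenerateMapError` naming the channel.
    """
    maps = np.asarray(pred_maps)
    if maps.ndim != 3 or maps.shape[-1] != 2:
        raise ValueError(f"expected (H, W, 2) maps, got {maps.shape}")
    points = []
    for ch, name in ((0, "anterior"), (1, "posterior")):
        try:
            points.append(decode_map(maps[..., ch], method=method))
        except DegenerateMapError:
            raise DegenerateMapError(
                f"all-zero {name} (channel {ch}) localization map")
    return points[0], points[1]


def midline_from_points(ap, pp) -> Midline:
    """Midline through the two anchors; direction is the unit vector pp->ap."""
    ap = (float(ap[0]), float(ap[1]))
    pp = (float(pp[0]), float(pp[1]))
    dx, dy = ap[0] - pp[0], ap[1] - pp[1]
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise ValueError("ap and pp coincide; midline undefined")
    return Midline(ap=ap, pp=pp, direction=(dx / norm, dy / norm))


def moving_median_filter(traj: np.ndarray, window: int) -> np.ndarray:
    """Moving median over frames, independently per coordinate.

    The series is padded with ``ceil((w-1)/2)`` replicates of the first value
    and ``floor((w-1)/2)`` replicates of the last, so the output has exactly
    as many frames as the input.  For even windows the median is the mean of
    the two central order statistics.
    """
    traj = np.asarray(traj, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    t = traj.shape[0]
    if window > 4 * t:
        warnings.warn(
            f"filter window {window} much longer than the video ({t} frames);"
            " output dominated by edge padding", stacklevel=2)
    if window == 1:
        return traj.copy()
    lead = int(np.ceil((window - 1) / 2))
    trail = (window - 1) // 2
    flat = traj.reshape(t, -1)
    padded = np.concatenate(
        [np.repeat(flat[:1], lead, axis=0), flat,
         np.repeat(flat[-1:], trail, axis=0)], axis=0)
    windows = np.lib.stride_tricks.sliding_window_view(padded, window, axis=0)
    out = np.median(windows, axis=-1)
    return out.reshape(traj.shape)


def _model_input_size(model) -> tuple[int, int]:
    return tuple(model.config.input_size)


def predict_video(model, frames: np.ndarray, window: int = 1,
                  decode_method: str = "centroid"
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Run a model over a preprocessed clip and decode per-frame keypoints.

    ``frames``: (T, H, W) array of images already normalized to [-1, 1] at
    the model's input size.  Returns ``(trajectory, seg_maps)`` where
    ``trajectory`` is (T, 2, 2) decoded (ap, pp) points — median-filtered
    with ``window`` if > 1 — and ``seg_maps`` is the (T, H, W) stack of
    segmentation probabilities.

    Temporal handling follows the model's configuration: frame-by-frame for
    2-D models, a sliding window with edge replication (predicting the center
    frame) for the channels mode, and whole-clip inference for the conv3d and
    convlstm modes.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3:
        raise ValueError(f"frames must be (T, H, W), got {frames.shape}")
    t = frames.shape[0]
    mode = model.config.temporal_mode
    with nn.no_grad():
        if mode == "none":
            out = model(frames[..., None])
            seg = out["seg"].data[..., 0]
            kmaps = out["keypoints"].data
        elif mode == "channels":
            nf = model.config.n_frames
            half_lead = (nf - 1) // 2
            half_trail = nf - 1 - half_lead
            padded = np.concatenate(
                [np.repeat(frames[:1], half_lead, axis=0), frames,
                 np.repeat(frames[-1:], half_trail, axis=0)], axis=0)
            stacks = np.stack(
                [padded[i:i + nf].transpose(1, 2, 0) for i in range(t)])
            out = model(stacks)
            seg = out["seg"].data[..., 0]
            kmaps = out["keypoints"].data
        else:  # conv3d / convlstm: whole clip at once
            out = model(frames[None, ..., None])
            seg = out["seg"].data[0, ..., 0]
            kmaps = out["keypoints"].data[0]
    traj = np.array([decode_keypoints(kmaps[i], method=decode_method)
                     for i in range(t)], dtype=float)
    if window > 1:
        traj = moving_median_filter(traj, window)
    return traj, seg
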