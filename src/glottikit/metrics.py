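"""Evaluation metrics: MAPE on keypoint coordinates, IoU on masks, and
per-video trajectory jitter.

MAPE is computed per image over the four coordinate scalars
(ap_x, ap_y, pp_x, pp_y) as ``(100/n) * sum |y_i - y_true,i| / |y_true,i|``.
Coordinates are shifted to a 1-based pixel convention before division, so a
true point on the first row or column never produces a zero denominator; this
convention is exposed via ``one_based``.

Jitter is the population standard deviation over frames of the Euclidean
distance between the predicted point and the constant true position — a
measure of frame-to-frame instability of the detected midline anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = [
    "mape",
    "mape_per_image",
    "iou",
    "trajectory_jitter",
    "summarize",
    "EvalReport",
]


def _coords(points) -> np.ndarray:
    """(ap, pp) pair(s) -> flat array(s) [ap_x, ap_y, pp_x, pp_y]."""
    arr = np.asarray(points, dtype=float)
    return arr.reshape(arr.shape[:-2] + (4,))


def mape_per_image(pred_points, true_points, one_based: bool = True
                   ) -> np.ndarray:
    """MAPE (%) for each image; inputs shaped (n_images, 2, 2) as (ap, pp)
    point pairs in (x, y) pixel coordinates."""
    pred = _coords(pred_points)
    true = _coords(true_points)
    if pred.shape != true.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != truth shape {true.shape}")
    if pred.ndim == 1:
        pred, true = pred[None], true[None]
    if one_based:
        pred = pred + 1.0
        true = true + 1.0
    if np.any(true == 0):
        raise ValueError("true coordinate equal to 0; use one_based=True")
    return 100.0 * np.mean(np.abs((pred - true) / true), axis=-1)


def mape(pred_points, true_points, one_based: bool = True) -> float:
    """Dataset MAPE (%): the per-image scores averaged over images."""
    return float(np.mean(mape_per_image(pred_points, true_points, one_based)))


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Both masks empty is scored 1.0: an empty prediction for a fully closed
    glottis is a correct prediction.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a > 0.5
    b = b > 0.5
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def trajectory_jitter(pred_traj, true_points) -> dict[str, float]:
    """Std of the per-frame Euclidean error for each midline anchor.

    ``pred_traj``: (T, 2, 2) per-frame (ap, pp) predictions;
    ``true_points``: the constant (ap, pp) ground truth of the video.
    Returns ``{"ap_std": ..., "pp_std": ...}`` in pixels (population std).
    """
    traj = np.asarray(pred_traj, dtype=float)
    if traj.ndim != 3 or traj.shape[1:] != (2, 2):
        raise ValueError(f"trajectory must be (T, 2, 2), got {traj.shape}")
    if traj.shape[0] < 2:
        raise ValueError("jitter needs at least 2 frames")
    true = np.asarray(true_points, dtype=float).reshape(2, 2)
    out = {}
    for idx, name in ((0, "ap_std"), (1, "pp_std")):
        d = np.linalg.norm(traj[:, idx, :] - true[idx], axis=1)
        out[name] = float(np.std(d))  # population (ddof=0)
    return out


def summarize(per_image_scores) -> dict[str, float]:
    """Distribution summary {median, q1, q3, min, max} with linearly
    interpolated quantiles."""
    scores = np.asarray(list(per_image_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot summarize an empty score list")
    return {
        "median": float(np.percentile(scores, 50, method="linear")),
        "q1": float(np.percentile(scores, 25, method="linear")),
        "q3": float(np.percentile(scores, 75, method="linear")),
        "min": float(scores.min()),
        "max": float(scores.max()),
    }


@dataclass(frozen=True)
class EvalReport:
    """Joint evaluation summary for a dataset."""

    mape_summary: dict        # {median, q1, q3, min, max} in %
    mean_iou: float | None    # fraction in [0, 1]; None if no masks compared
    jitter: dict              # video_id -> {ap_std, pp_std} in pixels

    def __post_init__(self):
        s = self.mape_summary
        if not (s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]):
            raise ValueError("inconsistent MAPE summary ordering")
        if self.mean_iou is not None and not (0 <= self.mean_iou <= 1):
            raise ValueError("mean IoU must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "EvalReport":
        return EvalReport(**json.loads(text))
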