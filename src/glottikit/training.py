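"""Losses, learning-rate policies, annotation-consistent augmentation, and
the training loop.

The two tasks are optimized jointly with Adam: soft Dice loss for the
segmentation head and pixelwise MSE for the keypoint localization maps,
combined with configurable weights (default 1:1).  Validation is split by
video so frames of one clip never straddle the train/validation boundary,
and the retained checkpoint is the epoch with the best validation MAPE.

Geometric augmentations (horizontal flip, rotation) transform the image and
mask by resampling but move the annotated points analytically and rebuild
their localization maps from the transformed points, so the keypoint labels
stay exact.  Photometric augmentations (blur, random gamma, Gaussian noise)
touch only the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import scipy.ndimage as ndi

from . import nn
from .inference import decode_keypoints
from .metrics import iou as iou_metric, mape_per_image
from .preprocessing import PreparedSample, make_target_map

__all__ = [
    "TrainConfig",
    "AugmentationConfig",
    "dice_loss",
    "keypoint_loss",
    "combined_loss",
    "lr_schedule",
    "augment",
    "augment_dataset",
    "split_videos",
    "train",
    "TrainingDiverged",
]

DICE_EPS = 1.0  # smoothing; keeps the loss finite on closed-glottis frames


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30            # the 2-D training length; 3-D runs use 100
    lr_policy: str = "scheduler2"
    lr0: float = 3e-3
    batch_size: int = 8
    val_fraction: float = 0.10
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_seg, w_pts)

    def validate(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError(
                f"val_fraction must be in (0, 1), got {self.val_fraction}")
        w_seg, w_pts = self.loss_weights
        if w_seg < 0 or w_pts < 0 or (w_seg == 0 and w_pts == 0):
            raise ValueError(
                "loss weights must be non-negative and not both zero")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class AugmentationConfig:
    rotation: bool = True
    horizontal_flip: bool = True
    blur: bool = True
    random_gamma: bool = True
    gaussian_noise: bool = True
    augment_factor: int = 10
    rotation_range: float = 30.0   # degrees, uniform in +-range
    blur_sigma: tuple[float, float] = (0.5, 1.5)
    gamma_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: tuple[float, float] = (0.005, 0.03)
    radius: float | None = None    # target-map radius; inferred if None


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _check_shapes(a, b, what):
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if tuple(sa) != tuple(sb):
        raise ValueError(f"{what}: shape mismatch {tuple(sa)} vs {tuple(sb)}")


def dice_loss(pred_mask, true_mask):
    """Soft Dice loss ``1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)``
    with eps = 1.  Accepts tensors or arrays; returns a scalar of kind
    matching the prediction input."""
    _check_shapes(pred_mask, true_mask, "dice_loss")
    p = nn.as_tensor(pred_mask)
    t = nn.as_tensor(true_mask)
    num = (p * t).sum() * 2.0 + DICE_EPS
    den = p.sum() + t.sum() + DICE_EPS
    out = 1.0 - num / den
    return out if isinstance(pred_mask, nn.Tensor) else float(out.data)


def keypoint_loss(pred_maps, target_maps):
    """Mean squared error over all pixels of both localization channels."""
    _check_shapes(pred_maps, target_maps, "keypoint_loss")
    p = nn.as_tensor(pred_maps)
    t = nn.as_tensor(target_maps)
    diff = p - t
    out = (diff * diff).mean()
    return out if isinstance(pred_maps, nn.Tensor) else float(out.data)


def combined_loss(outputs, targets, weights=(1.0, 1.0)):
    """``w_seg * dice + w_pts * mse`` for a model output dict and a target
    dict with keys 'seg' and 'keypoints'."""
    w_seg, w_pts = weights
    if w_seg < 0 or w_pts < 0:
        raise ValueError("loss weights must be non-negative")
    total = None
    if w_seg:
        total = dice_loss(outputs["seg"], targets["seg"]) * w_seg
    if w_pts:
        part = keypoint_loss(outputs["keypoints"], targets["keypoints"]) * w_pts
        total = part if total is None else total + part
    return total


# ---------------------------------------------------------------------------
# learning-rate policies
# ---------------------------------------------------------------------------


def lr_schedule(policy: str, lr0: float, epoch: int) -> float:
    """Learning rate at a (0-based) epoch.

    ``constant``: lr0.  ``exp_decay``: lr0 * 0.95**epoch.
    ``scheduler1``: step decay, halving every 10 epochs.
    ``scheduler2``: linear warmup over 3 epochs to lr0, then 0.9**k decay.
    The two named schedulers are this package's presets.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if policy == "constant":
        return lr0
    if policy == "exp_decay":
        return lr0 * 0.95 ** epoch
    if policy == "scheduler1":
        return lr0 * 0.5 ** (epoch // 10)
    if policy == "scheduler2":
        if epoch < 3:
            return lr0 * (epoch + 1) / 3.0
        return lr0 * 0.9 ** (epoch - 3)
    raise ValueError(f"unknown lr policy {policy!r}")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def flip_point(p, width: int):
    return (width - 1 - p[0], p[1])


def rotate_point(p, angle_deg: float, center):
    """Rotate a point by the same screen-space angle ndimage.rotate applies
    to image content (positive = counter-clockwise on screen)."""
    theta = math.radians(angle_deg)
    cx, cy = center
    dx, dy = p[0] - cx, p[1] - cy
    # y axis points down, so the screen-CCW rotation matrix is transposed
    return (cx + dx * math.cos(theta) + dy * math.sin(theta),
            cy - dx * math.sin(theta) + dy * math.cos(theta))


def _infer_radius(sample: PreparedSample) -> float:
    area = float(sample.target_maps[..., 0].sum())
    if area <= 0:
        area = float(sample.target_maps[..., 1].sum())
    return max(math.sqrt(area / math.pi), 1.0) if area > 0 else 1.0


class SampleRejected(RuntimeError):
    """A geometric transform moved a keypoint outside the image."""


def _augment_once(sample: PreparedSample, config: AugmentationConfig,
                  rng: np.random.Generator) -> PreparedSample:
    h, w = sample.image.shape
    image = sample.image.copy()
    mask = sample.mask.copy()
    ap, pp = sample.ap, sample.pp
    radius = config.radius if config.radius is not None else _infer_radius(sample)

    if config.horizontal_flip and rng.random() < 0.5:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()
        ap, pp = flip_point(ap, w), flip_point(pp, w)

    if config.rotation:
        angle = rng.uniform(-config.rotation_range, config.rotation_range)
        if abs(angle) > 1e-12:
            center = ((w - 1) / 2.0, (h - 1) / 2.0)
            ap_r = rotate_point(ap, angle, center)
            pp_r = rotate_point(pp, angle, center)
            inside = all(0 <= x <= w - 1 and 0 <= y <= h - 1
                         for x, y in (ap_r, pp_r))
            if not inside:
                raise SampleRejected(
                    f"rotation by {angle:.1f} deg moved a point out of bounds")
            image = ndi.rotate(image, angle, reshape=False, order=1,
                               mode="nearest")
            mask = (ndi.rotate(mask.astype(float), angle, reshape=False,
                               order=0, mode="constant") > 0.5).astype(np.uint8)
            ap, pp = ap_r, pp_r

    if config.blur and rng.random() < 0.5:
        image = ndi.gaussian_filter(image, rng.uniform(*config.blur_sigma))
    if config.random_gamma and rng.random() < 0.5:
        g = rng.uniform(*config.gamma_range)
        image = 2.0 * np.clip((image + 1.0) / 2.0, 0, 1) ** g - 1.0
    if config.gaussian_noise and rng.random() < 0.5:
        image = image + rng.normal(0, rng.uniform(*config.noise_sd),
                                   size=image.shape)
    image = np.clip(image, -1.0, 1.0).astype(np.float32)

    maps = np.stack([make_target_map(ap, (h, w), radius),
                     make_target_map(pp, (h, w), radius)], axis=-1)
    return dc_replace(sample, image=image, mask=mask,
                      target_maps=maps.astype(np.float32), ap=ap, pp=pp)


def augment(sample: PreparedSample, config: AugmentationConfig,
            seed: int | np.random.Generator = 0,
            max_tries: int = 10) -> PreparedSample:
    """One random augmented copy of a prepared sample.

    Rotations that would carry a keypoint outside the image are rejected and
    the transform resampled (up to ``max_tries``, after which the sample is
    returned unrotated but photometrically augmented).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    for _ in range(max_tries):
        try:
            return _augment_once(sample, config, rng)
        except SampleRejected:
            continue
    return _augment_once(sample, dc_replace(config, rotation=False), rng)


def augment_dataset(videos, config: AugmentationConfig, seed: int = 0):
    """Expand a list of per-video sample lists by ``augment_factor`` (the
    originals plus factor-1 augmented copies of each video)."""
    rng = np.random.default_rng(seed)
    out = []
    for video in videos:
        out.append(list(video))
        for _ in range(max(config.augment_factor - 1, 0)):
            out.append([augment(s, config, rng) for s in video])
    return out


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def split_videos(videos, val_fraction: float, rng: np.random.Generator):
    """Video-disjoint train/validation split; at least one video per side."""
    n = len(videos)
    if n < 2:
        raise ValueError("need at least 2 videos to split train/validation")
    order = rng.permutation(n)
    n_val = int(np.clip(round(val_fraction * n), 1, n - 1))
    val_idx = set(order[:n_val].tolist())
    train = [videos[i] for i in range(n) if i not in val_idx]
    val = [videos[i] for i in range(n) if i in val_idx]
    return train, val


def _batches(samples, batch_size, rng):
    order = rng.permutation(len(samples))
    for start in range(0, len(samples), batch_size):
        idx = order[start:start + batch_size]
        batch = [samples[i] for i in idx]
        x = np.stack([s.image for s in batch])[..., None]
        seg = np.stack([s.mask for s in batch]).astype(np.float32)[..., None]
        maps = np.stack([s.target_maps for s in batch])
        yield x, {"seg": nn.as_tensor(seg), "keypoints": nn.as_tensor(maps)}


def _evaluate(model, samples, weights):
    """Validation pass: mean combined loss, mean IoU, mean MAPE."""
    losses, ious, preds, trues = [], [], [], []
    with nn.no_grad():
        for s in samples:
            out = model(s.image[None, ..., None])
            targets = {
                "seg": nn.as_tensor(s.mask.astype(np.float32)[None, ..., None]),
                "keypoints": nn.as_tensor(s.target_maps[None]),
            }
            losses.append(float(combined_loss(out, targets, weights).data))
            ious.append(iou_metric(out["seg"].data[0, ..., 0] > 0.5, s.mask))
            try:
                ap, pp = decode_keypoints(out["keypoints"].data[0])
                preds.append((ap, pp))
                trues.append((s.ap, s.pp))
            except ValueError:
                preds.append(((0.0, 0.0), (0.0, 0.0)))
                trues.append((s.ap, s.pp))
    val_mape = float(np.mean(mape_per_image(np.array(preds), np.array(trues))))
    return float(np.mean(losses)), float(np.mean(ious)), val_mape


def train(model, videos, train_config: TrainConfig,
          augment_config: AugmentationConfig | None = None):
    """Train a 2-D per-frame model on a list of videos.

    ``videos``: list of lists of :class:`PreparedSample` (one inner list per
    video).  Returns ``(model, history)`` where the model carries the weights
    of the epoch with the lowest validation MAPE and ``history`` is a list of
    per-epoch dicts (train_loss, val_loss, val_iou, val_mape, lr).
    """
    train_config.validate()
    videos = [list(v) for v in videos]
    if not videos or not any(videos):
        raise ValueError("empty dataset")
    rng = np.random.default_rng(train_config.seed)
    train_videos, val_videos = split_videos(
        videos, train_config.val_fraction, rng)
    if augment_config is not None:
        train_videos = augment_dataset(
            train_videos, augment_config,
            seed=int(rng.integers(2 ** 31)))
    train_samples = [s for v in train_videos for s in v]
    val_samples = [s for v in val_videos for s in v]

    opt = nn.Adam(model.parameters(), lr=train_config.lr0)
    weights = train_config.loss_weights
    history = []
    best = (np.inf, None)
    for epoch in range(train_config.epochs):
        opt.lr = lr_schedule(train_config.lr_policy, train_config.lr0, epoch)
        epoch_losses = []
        for x, targets in _batches(train_samples, train_config.batch_size, rng):
            out = model(x, training=True)
            loss = combined_loss(out, targets, weights)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}; "
                    "lower the learning rate")
            opt.zero_grad()
            nn.backward(loss)
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss, val_iou, val_mape = _evaluate(model, val_samples, weights)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_iou": val_iou,
            "val_mape": val_mape,
            "lr": opt.lr,
        })
        if val_mape < best[0]:
            best = (val_mape, model.state_arrays())
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, history
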