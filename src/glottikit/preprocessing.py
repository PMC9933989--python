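"""Image/mask preparation and keypoint target-map construction.

The network consumes grayscale images mapped linearly to [-1, 1] and binary
masks in {0, 1}.  Anterior/posterior points are supervised through
*localization maps*: image-sized binary grids in which the point is marked as
a filled disk of a configurable radius.  The default radius is 15 px at the
reference 512x256 resolution and is meant to be scaled proportionally with
the image (7.5 px at 256x128).

Coordinates follow the (x, y) = (column, row), 0-based, origin top-left
convention throughout the package; sub-pixel positions are allowed and disk
membership is evaluated against the float center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "PreparedSample",
    "make_target_map",
    "make_gaussian_map",
    "prepare",
    "prepare_video",
    "scale_radius",
    "DEFAULT_RADIUS",
    "REFERENCE_SIZE",
    "PointOutsideImage",
]

DEFAULT_RADIUS = 15.0
REFERENCE_SIZE = (512, 256)  # (H, W) at which DEFAULT_RADIUS applies


class PointOutsideImage(ValueError):
    pass


@dataclass(frozen=True)
class PreparedSample:
    """Model-ready sample: image in [-1, 1], mask in {0, 1}, target maps."""

    image: np.ndarray        # (H, W) float32 in [-1, 1]
    mask: np.ndarray         # (H, W) uint8 in {0, 1}
    target_maps: np.ndarray  # (H, W, 2) float32 in {0, 1}; ch 0 = AP, 1 = PP
    ap: tuple[float, float]
    pp: tuple[float, float]
    video_id: str = ""
    frame_idx: int = 0


def scale_radius(out_size: tuple[int, int],
                 radius: float = DEFAULT_RADIUS,
                 reference: tuple[int, int] = REFERENCE_SIZE) -> float:
    """Radius scaled proportionally from the reference resolution."""
    return radius * out_size[0] / reference[0]


def make_target_map(point: tuple[float, float], size: tuple[int, int],
                    radius: float) -> np.ndarray:
    """Binary disk localization map for one keypoint.

    ``grid[r, c] = 1`` iff ``(c - x)^2 + (r - y)^2 <= radius^2`` (inclusive
    boundary), clipped at image borders.  A point so far outside the grid
    that no pixel qualifies yields an all-zero map and a warning.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    h, w = size
    x, y = float(point[0]), float(point[1])
    grid = np.zeros((h, w), dtype=np.float32)
    # only evaluate the bounding box of the disk
    r0 = max(int(np.floor(y - radius)), 0)
    r1 = min(int(np.ceil(y + radius)), h - 1)
    c0 = max(int(np.floor(x - radius)), 0)
    c1 = min(int(np.ceil(x + radius)), w - 1)
    if r0 <= r1 and c0 <= c1:
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        inside = (cc - x) ** 2 + (rr - y) ** 2 <= radius ** 2
        grid[r0:r1 + 1, c0:c1 + 1] = inside
    if grid.sum() == 0:
        warnings.warn(
            f"keypoint {point} with radius {radius} covers no pixel of a "
            f"{h}x{w} grid; target map is all zero", stacklevel=2)
    return grid


def make_gaussian_map(point: tuple[float, float], size: tuple[int, int],
                      radius: float) -> np.ndarray:
    """Smooth alternative target: Gaussian bump with sigma = radius / 2."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    h, w = size
    x, y = float(point[0]), float(point[1])
    rr, cc = np.mgrid[0:h, 0:w]
    sigma = radius / 2.0
    return np.exp(-((cc - x) ** 2 + (rr - y) ** 2) / (2 * sigma ** 2)
                  ).astype(np.float32)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion for (H, W, 3) inputs; identity for grayscale."""
    if image.ndim == 3:
        return image @ np.array([0.2989, 0.5870, 0.1140])
    return image


def prepare(image: np.ndarray, mask: np.ndarray,
            ap: tuple[float, float], pp: tuple[float, float],
            out_size: tuple[int, int],
            radius: float,
            gaussian_targets: bool = False,
            video_id: str = "", frame_idx: int = 0) -> PreparedSample:
    """Resize and normalize one annotated frame and build its target maps.

    The image is converted to grayscale (luminance), bilinearly resized to
    ``out_size = (H, W)`` and mapped linearly from [0, 1] to [-1, 1]; the mask
    is nearest-neighbor resized and re-binarized; points are scaled by the
    resize factors and the localization maps rebuilt at the output size.
    """
    h_out, w_out = out_size
    gray = np.asarray(to_grayscale(np.asarray(image, dtype=float)))
    h_in, w_in = gray.shape
    for name, (x, y) in (("ap", ap), ("pp", pp)):
        if not (0 <= x <= w_in - 1 and 0 <= y <= h_in - 1):
            raise PointOutsideImage(
                f"{name} point {x, y} outside {h_in}x{w_in} image")
    if (h_out, w_out) == (h_in, w_in):
        resized = gray
        mask_out = (np.asarray(mask) > 0).astype(np.uint8)
    else:
        resized = _sk_resize(gray, (h_out, w_out), order=1,
                             anti_aliasing=False, preserve_range=True)
        mask_out = _sk_resize(np.asarray(mask, dtype=float), (h_out, w_out),
                              order=0, anti_aliasing=False,
                              preserve_range=True)
        mask_out = (mask_out > 0.5).astype(np.uint8)
    sx, sy = w_out / w_in, h_out / h_in
    ap_s = (ap[0] * sx, ap[1] * sy)
    pp_s = (pp[0] * sx, pp[1] * sy)
    for name, (x, y) in (("ap", ap_s), ("pp", pp_s)):
        if not (0 <= x <= w_out - 1 + 1e-9 and 0 <= y <= h_out - 1 + 1e-9):
            raise PointOutsideImage(
                f"{name} point {x, y} outside resized {h_out}x{w_out} image")
    maker = make_gaussian_map if gaussian_targets else make_target_map
    maps = np.stack([maker(ap_s, (h_out, w_out), radius),
                     maker(pp_s, (h_out, w_out), radius)], axis=-1)
    image_out = (2.0 * resized - 1.0).astype(np.float32)
    return PreparedSample(image=image_out, mask=mask_out,
                          target_maps=maps.astype(np.float32),
                          ap=ap_s, pp=pp_s,
                          video_id=video_id, frame_idx=frame_idx)


def prepare_video(video, out_size: tuple[int, int], radius: float,
                  video_id: str = "", **kw) -> list[PreparedSample]:
    """Apply :func:`prepare` to every frame of a video sample."""
    return [
        prepare(f.image, f.mask, f.ap, f.pp, out_size, radius,
                video_id=video_id, frame_idx=i, **kw)
        for i, f in enumerate(video.frames)
    ]
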