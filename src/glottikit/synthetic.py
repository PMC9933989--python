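"""Synthetic high-speed-videoendoscopy clips with ground truth.

Each clip shows a lens-shaped (vesica) glottal opening oscillating over a
cycle between two fixed anatomical landmarks: the anterior point (AP) and the
posterior point (PP).  The opening is dark against a brighter background, as
the glottal gap appears in endoscopic footage, with additive Gaussian pixel
noise.  The AP/PP pair is constant across the frames of one clip, which is the
regime in which a per-video glottal midline is well defined.

The lens is the intersection of two circular discs whose boundary arcs pass
through AP and PP; its half-width at frame ``t`` scales with
``|sin(pi * t / cycle_frames)|`` so that phase 0 is full glottal closure.
All randomness is driven by explicit integer seeds; identical parameters give
bit-identical clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SynthParams",
    "AnnotatedFrame",
    "VideoSample",
    "generate_video",
    "generate_dataset",
    "default_param_ranges",
    "DEFAULT_PARAM_RANGES",
]

_INSIDE_LEVEL = 0.1  # intensity of the open glottal gap (dark)


class ParameterError(ValueError):
    """A synthesis parameter violates its constraint; names the field."""


@dataclass(frozen=True)
class SynthParams:
    """Geometry, photometry and seeding of one synthetic clip.

    All lengths are in pixels, intensities on the [0, 1] scale.
    ``midline_angle`` is measured in degrees from the vertical image axis;
    ``glottis_length`` is the AP-PP distance and ``max_half_width`` the peak
    half-opening of the lens at mid-phase.
    """

    height: int = 64
    width: int = 32
    n_frames: int = 30
    cycle_frames: int = 12
    midline_angle: float = 0.0
    midline_center: tuple[float, float] = (16.0, 32.0)
    glottis_length: float = 24.0
    max_half_width: float = 5.0
    noise_sd: float = 0.03
    background_level: float = 0.65
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ParameterError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.cycle_frames < 2:
            raise ParameterError(
                f"cycle_frames must be >= 2, got {self.cycle_frames}")
        if self.max_half_width < 1:
            raise ParameterError(
                f"max_half_width must be >= 1, got {self.max_half_width}")
        if not self.glottis_length < min(self.height, self.width):
            raise ParameterError(
                f"glottis_length {self.glottis_length} must be < "
                f"min(height, width) = {min(self.height, self.width)}")
        if not (0 <= self.background_level <= 1):
            raise ParameterError(
                f"background_level must be in [0,1], got {self.background_level}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        ap, pp = self.axis_points()
        for name, (x, y) in (("ap", ap), ("pp", pp)):
            if not (0 <= x <= self.width - 1 and 0 <= y <= self.height - 1):
                raise ParameterError(
                    f"{name} {x, y} outside {self.height}x{self.width} frame; "
                    "adjust midline_center/glottis_length")

    def axis_points(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(ap, pp) lens tips in (x, y) pixel coordinates (AP above center)."""
        theta = np.deg2rad(self.midline_angle)
        vx, vy = np.sin(theta), np.cos(theta)  # unit vector along the midline
        cx, cy = self.midline_center
        h = self.glottis_length / 2.0
        ap = (cx - h * vx, cy - h * vy)
        pp = (cx + h * vx, cy + h * vy)
        return ap, pp


@dataclass(frozen=True)
class AnnotatedFrame:
    """One grayscale frame plus its mask and AP/PP annotation."""

    image: np.ndarray          # (H, W) float in [0, 1]
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    ap: tuple[float, float]    # (x, y), sub-pixel
    pp: tuple[float, float]


@dataclass(frozen=True)
class VideoSample:
    """Ordered frames sharing one constant (ap, pp) annotation."""

    frames: tuple[AnnotatedFrame, ...]
    params: SynthParams | None = None

    @property
    def ap(self) -> tuple[float, float]:
        return self.frames[0].ap

    @property
    def pp(self) -> tuple[float, float]:
        return self.frames[0].pp

    def __len__(self) -> int:
        return len(self.frames)


def lens_half_width_profile(s: np.ndarray, length: float, half_width: float
                            ) -> np.ndarray:
    """Half-width of a circular-arc lens at signed axial offset ``s``.

    The lens through two tips a distance ``length`` apart with sagitta
    ``half_width`` is bounded by arcs of circles of radius
    R = ((L/2)^2 + w^2) / (2w); the half-width at offset s from the lens
    center is sqrt(R^2 - s^2) - (R - w), clipped at 0.
    """
    if half_width <= 0:
        return np.zeros_like(s)
    half_len = length / 2.0
    radius = (half_len ** 2 + half_width ** 2) / (2.0 * half_width)
    inside = np.abs(s) <= half_len
    profile = np.zeros_like(s, dtype=float)
    profile[inside] = np.sqrt(radius ** 2 - s[inside] ** 2) - (radius - half_width)
    return np.clip(profile, 0.0, None)


def _rasterize_lens(params: SynthParams, half_width: float) -> np.ndarray:
    """Binary mask of the lens with the given instantaneous half-width."""
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    theta = np.deg2rad(params.midline_angle)
    vx, vy = np.sin(theta), np.cos(theta)
    cx, cy = params.midline_center
    dx, dy = xx - cx, yy - cy
    s = dx * vx + dy * vy           # along-axis coordinate
    u = -dx * vy + dy * vx          # across-axis coordinate
    hw = lens_half_width_profile(s, params.glottis_length, half_width)
    return ((np.abs(u) <= hw) & (hw > 0)).astype(np.uint8)


def half_width_at_frame(params: SynthParams, t: int) -> float:
    """Instantaneous half-opening; zero at phase 0 (full closure)."""
    return params.max_half_width * abs(
        np.sin(np.pi * t / params.cycle_frames))


def generate_video(params: SynthParams) -> VideoSample:
    """Render one synthetic clip with per-frame masks and constant AP/PP.

    Raises :class:`ParameterError` naming the offending field for invalid
    parameters.  Output is bit-identical for identical params (incl. seed).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ap, pp = params.axis_points()
    frames = []
    for t in range(params.n_frames):
        mask = _rasterize_lens(params, half_width_at_frame(params, t))
        image = np.full((params.height, params.width),
                        params.background_level, dtype=float)
        image[mask == 1] = _INSIDE_LEVEL
        if params.noise_sd > 0:
            image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
        image = np.clip(image, 0.0, 1.0).astype(np.float32)
        frames.append(AnnotatedFrame(image=image, mask=mask, ap=ap, pp=pp))
    return VideoSample(frames=tuple(frames), params=params)


def default_param_ranges(height: int, width: int
                         ) -> dict[str, tuple[float, float]]:
    """Per-video parameter ranges emulating inter-patient variability.

    Midline orientation is a modest rotation from vertical, glottal length
    roughly 0.6-0.9 of the short frame side, peak half-opening about a tenth
    of it, with moderate sensor noise.  Geometric ranges scale with the frame
    so the same relative anatomy is produced at any resolution.
    """
    m = min(height, width)
    return {
        "midline_angle": (-15.0, 15.0),
        "glottis_length": (0.56 * m, 0.87 * m),
        "max_half_width": (max(0.09 * m, 1.0), max(0.22 * m, 1.5)),
        "noise_sd": (0.01, 0.05),
        "background_level": (0.55, 0.75),
        "cycle_frames": (10, 14),
    }


DEFAULT_PARAM_RANGES = default_param_ranges(64, 32)


def generate_dataset(
    n_videos: int,
    params_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    height: int = 64,
    width: int = 32,
    n_frames: int = 30,
) -> list[VideoSample]:
    """Draw ``n_videos`` clips with per-video parameters sampled uniformly.

    Each video gets an independent child seed derived from ``seed`` via
    ``numpy.random.SeedSequence.spawn``, so the dataset is reproducible and
    individual videos are decorrelated.
    """
    if n_videos < 1:
        raise ParameterError(f"n_videos must be >= 1, got {n_videos}")
    ranges = dict(default_param_ranges(height, width)
                  if params_ranges is None else params_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ParameterError(f"empty range for '{key}': ({lo}, {hi})")
    children = np.random.SeedSequence(seed).spawn(n_videos)
    videos = []
    for child in children:
        rng = np.random.default_rng(child)

        def draw(key, default):
            lo, hi = ranges.get(key, (default, default))
            return rng.uniform(lo, hi)

        glottis_length = draw("glottis_length", min(height, width) // 2 * 1.5)
        angle = draw("midline_angle", 0.0)
        # keep the axis comfortably inside the frame
        margin = 3.0
        theta = np.deg2rad(angle)
        half_span_y = abs(np.cos(theta)) * glottis_length / 2
        half_span_x = abs(np.sin(theta)) * glottis_length / 2
        ylo, yhi = half_span_y + margin, height - 1 - half_span_y - margin
        xlo = max(half_span_x + margin, width * 0.3)
        xhi = min(width - 1 - half_span_x - margin, width * 0.7)
        if yhi < ylo:
            ylo = yhi = (height - 1) / 2.0
        if xhi < xlo:
            xlo = xhi = (width - 1) / 2.0
        cy = rng.uniform(ylo, yhi)
        cx = rng.uniform(xlo, xhi)
        params = SynthParams(
            height=height,
            width=width,
            n_frames=n_frames,
            cycle_frames=int(round(draw("cycle_frames", 12))),
            midline_angle=angle,
            midline_center=(float(cx), float(cy)),
            glottis_length=float(glottis_length),
            max_half_width=float(draw("max_half_width", 5.0)),
            noise_sd=float(draw("noise_sd", 0.03)),
            background_level=float(draw("background_level", 0.65)),
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        videos.append(generate_video(params))
    return videos
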