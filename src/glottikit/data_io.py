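"""Read and write frame-stack datasets in a BAGLS-style layout.

Layout: a flat directory of 8-bit grayscale PNGs, one image and one mask per
frame (mask values {0, 255} on disk, {0, 1} in memory), plus a single CSV of
point annotations with header ``id,video_id,frame_idx,ap_x,ap_y,pp_x,pp_y``.
Filename patterns are configurable (defaults ``{id}.png`` / ``{id}_seg.png``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import AnnotatedFrame, VideoSample

__all__ = [
    "LayoutConfig",
    "DatasetRecord",
    "DatasetIndex",
    "read_dataset",
    "write_dataset",
    "load_video",
    "IndexingError",
    "AnnotationValidationError",
]

MASK_THRESHOLD = 127  # on read: pixel > 127 -> glottis


class IndexingError(RuntimeError):
    """Dataset layout is inconsistent (e.g. images without masks)."""


class AnnotationValidationError(ValueError):
    """An annotation refers to a point outside its image."""


@dataclass(frozen=True)
class LayoutConfig:
    image_pattern: str = "{id}.png"
    mask_pattern: str = "{id}_seg.png"
    annotations_name: str = "annotations.csv"


@dataclass(frozen=True)
class DatasetRecord:
    id: str
    image_path: Path
    mask_path: Path
    ap: tuple[float, float]
    pp: tuple[float, float]
    video_id: str
    frame_idx: int


@dataclass(frozen=True)
class DatasetIndex:
    root: Path
    records: tuple[DatasetRecord, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.records)

    def video_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.video_id, None)
        return list(seen)

    def by_video(self) -> dict[str, list[DatasetRecord]]:
        groups: dict[str, list[DatasetRecord]] = {}
        for r in self.records:
            groups.setdefault(r.video_id, []).append(r)
        for vid, recs in groups.items():
            recs.sort(key=lambda r: r.frame_idx)
        return groups


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(img, dtype=float) * 255.0), 0, 255
                   ).astype(np.uint8)


def read_image(path: Path) -> np.ndarray:
    """8-bit grayscale PNG -> float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float32)
    return arr / 255.0


def read_mask(path: Path) -> np.ndarray:
    """Mask PNG -> {0, 1} uint8; tolerant to anti-aliased masks (>127 -> 1)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > MASK_THRESHOLD).astype(np.uint8)


def read_dataset(root_path, layout: LayoutConfig | None = None) -> DatasetIndex:
    """Index a dataset directory, validating image/mask pairing and points.

    Raises :class:`IndexingError` listing ids with a missing mask (or image),
    and :class:`AnnotationValidationError` if any annotated point falls
    outside its image bounds.
    """
    layout = layout or LayoutConfig()
    root = Path(root_path)
    if not root.is_dir():
        raise IndexingError(f"dataset root {root} does not exist")
    ann_path = root / layout.annotations_name
    if not ann_path.is_file():
        raise IndexingError(f"missing annotation file {ann_path}")
    table = pd.read_csv(ann_path, dtype={"id": str, "video_id": str})
    required = {"id", "ap_x", "ap_y", "pp_x", "pp_y"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise IndexingError(
            f"annotation file lacks columns: {sorted(missing_cols)}")
    if "video_id" not in table.columns:
        table["video_id"] = table["id"]
    if "frame_idx" not in table.columns:
        table["frame_idx"] = 0

    records = []
    problems = []
    for row in table.itertuples(index=False):
        rid = str(row.id)
        image_path = root / layout.image_pattern.format(id=rid)
        mask_path = root / layout.mask_pattern.format(id=rid)
        if not image_path.is_file():
            problems.append(f"{rid}: missing image {image_path.name}")
            continue
        if not mask_path.is_file():
            problems.append(f"{rid}: missing mask {mask_path.name}")
            continue
        with Image.open(image_path) as im:
            w, h = im.size
        with Image.open(mask_path) as im:
            mw, mh = im.size
        if (w, h) != (mw, mh):
            problems.append(
                f"{rid}: image {w}x{h} and mask {mw}x{mh} dimensions differ")
            continue
        ap = (float(row.ap_x), float(row.ap_y))
        pp = (float(row.pp_x), float(row.pp_y))
        for name, (x, y) in (("ap", ap), ("pp", pp)):
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise AnnotationValidationError(
                    f"{rid}: {name} point {x, y} outside {w}x{h} image")
        records.append(DatasetRecord(
            id=rid, image_path=image_path, mask_path=mask_path,
            ap=ap, pp=pp, video_id=str(row.video_id),
            frame_idx=int(row.frame_idx)))
    if problems:
        raise IndexingError("dataset inconsistencies: " + "; ".join(problems))
    records.sort(key=lambda r: (r.video_id, r.frame_idx))
    _check_contiguous(records)
    return DatasetIndex(root=root, records=tuple(records))


def _check_contiguous(records) -> None:
    by_vid: dict[str, list[int]] = {}
    for r in records:
        by_vid.setdefault(r.video_id, []).append(r.frame_idx)
    bad = [vid for vid, idxs in by_vid.items()
           if sorted(idxs) != list(range(len(idxs)))]
    if bad:
        raise IndexingError(
            f"non-contiguous frame_idx within video(s): {bad}")


def write_dataset(samples, root_path, layout: LayoutConfig | None = None
                  ) -> list[Path]:
    """Write :class:`VideoSample` clips to disk; returns the file manifest.

    Images and masks are 8-bit PNG (mask stored as {0, 255}); one CSV holds
    all point annotations.  An empty sample list writes nothing and returns
    an empty manifest.
    """
    layout = layout or LayoutConfig()
    samples = list(samples)
    if not samples:
        return []
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    rows = []
    counter = 0
    for vid_idx, video in enumerate(samples):
        video_id = f"v{vid_idx:04d}"
        frames = video.frames if isinstance(video, VideoSample) else video
        for frame_idx, frame in enumerate(frames):
            rid = f"{counter}"
            counter += 1
            image_path = root / layout.image_pattern.format(id=rid)
            mask_path = root / layout.mask_pattern.format(id=rid)
            Image.fromarray(_to_uint8(frame.image)).save(image_path)
            Image.fromarray((frame.mask.astype(np.uint8) * 255)).save(mask_path)
            manifest.extend([image_path, mask_path])
            rows.append({
                "id": rid, "video_id": video_id, "frame_idx": frame_idx,
                "ap_x": frame.ap[0], "ap_y": frame.ap[1],
                "pp_x": frame.pp[0], "pp_y": frame.pp[1],
            })
    ann_path = root / layout.annotations_name
    pd.DataFrame(rows).to_csv(ann_path, index=False)
    manifest.append(ann_path)
    return manifest


def load_video(index: DatasetIndex, video_id: str) -> VideoSample:
    """Materialize one video's frames (images, masks, points) from disk."""
    recs = index.by_video().get(video_id)
    if not recs:
        raise KeyError(f"unknown video_id {video_id!r}")
    frames = [
        AnnotatedFrame(image=read_image(r.image_path),
                       mask=read_mask(r.mask_path), ap=r.ap, pp=r.pp)
        for r in recs
    ]
    return VideoSample(frames=tuple(frames))
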