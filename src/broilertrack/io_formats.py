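"""Detection/track file I/O and the shared geometric types.

Coordinate convention: pixels, origin at the image top-left, boxes stored as
(left, top, width, height).  The centroid of a box is (x + x_width/2,
y + y_height/2).  Frame indices are 0-based in memory; MOT-Challenge files
are 1-based on disk and are converted at the I/O boundary.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "BoundingBox",
    "Detection",
    "FrameDetections",
    "RunConfig",
    "ParseResult",
    "MotParseError",
    "read_mot_detections",
    "read_yolo_labels",
    "write_mot_tracks",
    "load_config",
]


class MotParseError(ValueError):
    """A detection/track file row that cannot be parsed at all."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel-space rectangle: minimum corner plus size."""

    x: float
    y: float
    x_width: float
    y_height: float

    def __post_init__(self) -> None:
        if not (self.x_width > 0 and self.y_height > 0):
            raise ValueError(f"box size must be positive, got {self}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"box corner must be non-negative, got {self}")

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x + self.x_width / 2.0, self.y + self.y_height / 2.0)


@dataclass(frozen=True)
class Detection:
    """One detector output: frame index, box, and confidence in [0, 1]."""

    frame: int
    box: BoundingBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass
class FrameDetections:
    """All detections of one frame."""

    frame: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.frame != self.frame:
                raise ValueError(
                    f"detection frame {d.frame} != group frame {self.frame}"
                )

    def __len__(self) -> int:
        return len(self.detections)


class RunConfig(BaseModel):
    """Pipeline-wide run parameters.

    Defaults mirror the reference pen setup: a 100 cm x 150 cm pen imaged
    top-down at 2592 x 1944 px, displacements sampled at 1 s intervals.
    ``max_gap`` (frames) defaults to 10 s of frames when not given.
    """

    frame_rate: float = Field(default=5.0, gt=0)
    sample_interval: float = Field(default=1.0, gt=0)
    distance_threshold: float = Field(default=30.0, gt=0)  # cm
    max_gap: int | None = Field(default=None)
    deadband: float = Field(default=0.5, ge=0)  # cm per 1-s step
    pen_width_cm: float = Field(default=100.0, gt=0)
    pen_height_cm: float = Field(default=150.0, gt=0)
    image_width_px: float = Field(default=2592.0, gt=0)
    image_height_px: float = Field(default=1944.0, gt=0)
    min_track_length: int = Field(default=5, gt=0)

    @model_validator(mode="after")
    def _fill_and_check(self) -> "RunConfig":
        if self.max_gap is None:
            object.__setattr__(self, "max_gap", max(1, round(10.0 * self.frame_rate)))
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.sample_interval * self.frame_rate < 1.0:
            raise ValueError(
                "sample_interval x frame_rate must be >= 1 "
                f"(got {self.sample_interval} x {self.frame_rate})"
            )
        return self


class ParseResult(Sequence):
    """Sequence of :class:`FrameDetections` plus the rejected-row count."""

    def __init__(self, frames: list[FrameDetections], n_warnings: int = 0):
        self.frames = frames
        self.n_warnings = n_warnings

    def __getitem__(self, i):
        return self.frames[i]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[FrameDetections]:
        return iter(self.frames)


def _group_by_frame(dets: list[Detection]) -> list[FrameDetections]:
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame, []).append(d)
    return [FrameDetections(f, by_frame[f]) for f in sorted(by_frame)]


def read_mot_detections(path: str | os.PathLike) -> ParseResult:
    """Read a MOT-Challenge CSV detection (or gt) file.

    Rows are ``frame,id,x,y,w,h,conf,...``; the id field is ignored here.
    Frames are converted from the file's 1-based indexing to 0-based.
    Rows with non-positive width/height, negative coordinates, or an
    out-of-range confidence are skipped and counted in ``n_warnings``;
    rows that are not numeric at all raise :class:`MotParseError` with the
    line number.
    """
    dets: list[Detection] = []
    n_warn = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MotParseError(
                    f"{path}:{lineno}: expected >= 7 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                x, y, w, h = (float(v) for v in parts[2:6])
                conf = float(parts[6])
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: {exc}") from exc
            conf = min(max(conf, 0.0), 1.0)
            try:
                dets.append(Detection(frame - 1, BoundingBox(x, y, w, h), conf))
            except ValueError:
                n_warn += 1
    return ParseResult(_group_by_frame(dets), n_warn)


def read_yolo_labels(
    directory: str | os.PathLike,
    image_width_px: float,
    image_height_px: float,
    *,
    clamp: bool = False,
) -> ParseResult:
    """Read a directory of YOLO txt label files, one per frame.

    Each file holds rows ``class cx cy w h`` in normalized [0, 1] image
    coordinates; the frame index is the trailing integer in the filename
    stem (``frame_000012.txt`` -> 12).  Boxes are converted to pixel
    top-left form.  Rows whose normalized values fall outside [0, 1], or
    whose converted corner is negative, are rejected (or clamped to the
    image when ``clamp=True``).
    """
    frames: list[FrameDetections] = []
    n_warn = 0
    names = sorted(n for n in os.listdir(directory) if n.endswith(".txt"))
    for name in names:
        stem = name[:-4]
        digits = ""
        for ch in reversed(stem):
            if ch.isdigit():
                digits = ch + digits
            else:
                break
        if not digits:
            raise MotParseError(f"cannot parse frame index from filename {name!r}")
        frame = int(digits)
        dets: list[Detection] = []
        with open(os.path.join(directory, name), "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                cx, cy, w, h = (float(v) for v in parts[1:5])
                conf = float(parts[5]) if len(parts) > 5 else 1.0
                if not all(0.0 <= v <= 1.0 for v in (cx, cy, w, h)):
                    n_warn += 1
                    continue
                x = (cx - w / 2.0) * image_width_px
                y = (cy - h / 2.0) * image_height_px
                wp = w * image_width_px
                hp = h * image_height_px
                if x < 0 or y < 0:
                    if clamp:
                        x, y = max(x, 0.0), max(y, 0.0)
                    else:
                        n_warn += 1
                        continue
                if wp <= 0 or hp <= 0:
                    n_warn += 1
                    continue
                dets.append(Detection(frame, BoundingBox(x, y, wp, hp), conf))
        frames.append(FrameDetections(frame, dets))
    frames.sort(key=lambda fd: fd.frame)
    return ParseResult(frames, n_warn)


def _fmt(v: float) -> str:
    # integers print without a decimal point so integer-px boxes round-trip
    # bit-exactly through the text file
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_mot_tracks(trajectories, path: str | os.PathLike) -> int:
    """Write trajectories in the MOT gt dialect ``frame,id,x,y,w,h,1,1,1``.

    Trajectories must carry per-point boxes in pixels (as produced by the
    tracker/merge pipeline).  Returns the number of rows written.  Frames
    are written 1-based.
    """
    rows: list[tuple[int, int, BoundingBox]] = []
    for traj in trajectories:
        boxes = getattr(traj, "boxes", None)
        if boxes is None:
            raise ValueError(f"trajectory {traj.bird_id} carries no boxes")
        for (frame, _x, _y), box in zip(traj.points, boxes):
            rows.append((frame, traj.bird_id, box))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for frame, tid, box in rows:
            fh.write(
                f"{frame + 1},{tid},{_fmt(box.x)},{_fmt(box.y)},"
                f"{_fmt(box.x_width)},{_fmt(box.y_height)},1,1,1\n"
            )
    return len(rows)


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML run configuration; missing keys take documented defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig(**data)


def euclidean(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])
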