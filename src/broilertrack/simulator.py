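"""Synthetic pen simulator.

Generates ground-truth bird trajectories with a pause-and-travel waypoint
walk inside a rectangular pen, and corrupts them into realistic detection
streams: occlusion-triggered dropouts, per-frame base misses with
multi-frame gap persistence, uniformly placed false positives, and Gaussian
centroid jitter.  Every downstream stage (tracker, re-association,
mobility) is scored against the ground truth these functions emit.

Motion model
------------
Each bird alternates between resting and travelling toward a uniformly
drawn waypoint.  At every frame, a resting bird stays put (with a small
sub-deadband perturbation) with probability ``pause_prob``; otherwise it
walks toward its waypoint at a speed drawn from
Normal(mean_speed_cm_s, 0.2 * mean_speed_cm_s), truncated at zero.  Bird
centers are confined to the pen deflated by the body radius, so a rendered
bounding box never leaves the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import BoundingBox, Detection, FrameDetections

__all__ = [
    "SimConfig",
    "NoiseConfig",
    "GroundTruthTrack",
    "PenCalibration",
    "simulate_motion",
    "render_detections",
    "inject_dropouts",
    "render_with_dropouts",
    "ssl_split",
    "path_length",
]


@dataclass(frozen=True)
class PenCalibration:
    """Linear cm <-> px mapping, assuming a nadir camera and the pen
    filling the frame.  Anisotropic because the pen is not square."""

    cm_per_px_x: float
    cm_per_px_y: float

    def __post_init__(self) -> None:
        if self.cm_per_px_x <= 0 or self.cm_per_px_y <= 0:
            raise ValueError("calibration factors must be positive")

    def cm_to_px(self, x_cm: float, y_cm: float) -> tuple[float, float]:
        return (x_cm / self.cm_per_px_x, y_cm / self.cm_per_px_y)

    def px_to_cm(self, x_px: float, y_px: float) -> tuple[float, float]:
        return (x_px * self.cm_per_px_x, y_px * self.cm_per_px_y)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth motion parameters.

    Defaults emulate the reference setup: a 100 cm x 150 cm pen holding 12
    birds, recorded for 15 min.  ``mean_speed_cm_s`` and ``pause_prob`` set
    the pause-and-travel regime; ``bird_radius_cm`` is half the body width
    and controls both box size and occlusion geometry.
    """

    n_birds: int = 12
    pen_width_cm: float = 100.0
    pen_height_cm: float = 150.0
    duration_s: float = 900.0
    frame_rate: float = 5.0
    mean_speed_cm_s: float = 5.0
    pause_prob: float = 0.5
    bird_radius_cm: float = 8.0
    min_separation_cm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if not (0.0 <= self.pause_prob <= 1.0):
            raise ValueError("pause_prob must be in [0,1]")
        for name in ("pen_width_cm", "pen_height_cm", "duration_s", "frame_rate",
                     "bird_radius_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_speed_cm_s < 0:
            raise ValueError("mean_speed_cm_s must be >= 0")
        if self.min_separation_cm is None:
            # birds are solid: centers keep at least one body radius apart
            # (bodies may still overlap visually, triggering occlusion)
            object.__setattr__(self, "min_separation_cm", self.bird_radius_cm)
        if self.min_separation_cm < 0:
            raise ValueError("min_separation_cm must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass(frozen=True)
class NoiseConfig:
    """Detection-corruption parameters.

    ``occlusion_dropout_prob`` fires only when two bird centers are closer
    than one body diameter; ``base_miss_prob`` fires independently every
    frame; an active dropout persists with ``gap_extension_prob``, which is
    what produces the multi-frame gaps that break tracker identities.
    """

    occlusion_dropout_prob: float = 0.0
    base_miss_prob: float = 0.0
    false_pos_rate: float = 0.0
    jitter_sd_cm: float = 0.0
    gap_extension_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("occlusion_dropout_prob", "base_miss_prob",
                     "gap_extension_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.false_pos_rate < 0 or self.jitter_sd_cm < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruthTrack:
    """One bird's dense ground-truth positions, ``(frame, x_cm, y_cm)``."""

    bird_id: int
    positions: list[tuple[int, float, float]] = field(default_factory=list)


def _reflect(v: float, lo: float, hi: float) -> float:
    # reflect into [lo, hi]; one pass suffices for per-frame step sizes
    if v < lo:
        v = 2 * lo - v
    if v > hi:
        v = 2 * hi - v
    return min(max(v, lo), hi)


def simulate_motion(config: SimConfig) -> list[GroundTruthTrack]:
    """Generate one dense ground-truth track per bird.

    Deterministic given ``config.seed``.  Resting perturbations are drawn
    with SD 0.004 * mean_speed_cm_s (0.02 cm at the 5 cm/s default) — far
    below any realistic deadband, so a resting bird contributes no
    measured displacement after deadband filtering, and a fully immobile
    configuration (zero mean speed) yields exactly zero path length.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    n = config.n_birds
    dt = 1.0 / config.frame_rate
    r = config.bird_radius_cm
    sep = config.min_separation_cm
    lo_x, hi_x = r, config.pen_width_cm - r
    lo_y, hi_y = r, config.pen_height_cm - r
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ValueError("bird_radius_cm too large for the pen")

    def clear_of_others(bird: int, px: float, py: float) -> bool:
        return all(
            math.hypot(px - xs[o], py - ys[o]) >= sep
            for o in range(n)
            if o != bird
        )

    # initial placement: rejection-sample positions respecting separation
    xs = np.empty(n)
    ys = np.empty(n)
    for b in range(n):
        for _ in range(10_000):
            px, py = rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)
            if all(math.hypot(px - xs[o], py - ys[o]) >= sep for o in range(b)):
                xs[b], ys[b] = px, py
                break
        else:
            raise ValueError("cannot place birds with the requested separation")

    wxs = rng.uniform(lo_x, hi_x, size=n)
    wys = rng.uniform(lo_y, hi_y, size=n)
    history = [[(0, float(xs[b]), float(ys[b]))] for b in range(n)]
    for frame in range(1, n_frames):
        for b in range(n):
            x, y = xs[b], ys[b]
            if rng.random() < config.pause_prob:
                sd = 0.004 * config.mean_speed_cm_s
                nx = _reflect(x + rng.normal(0.0, sd), lo_x, hi_x)
                ny = _reflect(y + rng.normal(0.0, sd), lo_y, hi_y)
            else:
                speed = max(
                    0.0,
                    rng.normal(config.mean_speed_cm_s,
                               0.2 * config.mean_speed_cm_s),
                )
                step = speed * dt
                dist = math.hypot(wxs[b] - x, wys[b] - y)
                if dist <= step or dist == 0.0:
                    nx, ny = wxs[b], wys[b]
                    wxs[b] = rng.uniform(lo_x, hi_x)
                    wys[b] = rng.uniform(lo_y, hi_y)
                else:
                    nx = _reflect(x + step * (wxs[b] - x) / dist, lo_x, hi_x)
                    ny = _reflect(y + step * (wys[b] - y) / dist, lo_y, hi_y)
            if clear_of_others(b, nx, ny):
                xs[b], ys[b] = nx, ny
            else:
                # blocked by another bird: stay put and pick a new waypoint
                wxs[b] = rng.uniform(lo_x, hi_x)
                wys[b] = rng.uniform(lo_y, hi_y)
            history[b].append((frame, float(xs[b]), float(ys[b])))
    return [GroundTruthTrack(b, history[b]) for b in range(n)]


def path_length(track: GroundTruthTrack, stride: int = 1) -> float:
    """Total polyline length in cm, optionally subsampled every ``stride``
    frames (stride = frame_rate gives the 1-s-sampled path length)."""
    pts = track.positions[::stride]
    return float(
        sum(
            math.hypot(x2 - x1, y2 - y1)
            for (_, x1, y1), (_, x2, y2) in zip(pts, pts[1:])
        )
    )


def _positions_array(tracks: Sequence[GroundTruthTrack]) -> np.ndarray:
    n_frames = len(tracks[0].positions)
    arr = np.empty((len(tracks), n_frames, 2))
    for i, t in enumerate(tracks):
        if len(t.positions) != n_frames:
            raise ValueError("tracks must be dense over the same frame range")
        arr[i] = [(x, y) for (_, x, y) in t.positions]
    return arr


def _make_detection(
    frame: int,
    cx_px: float,
    cy_px: float,
    half_w_px: float,
    half_h_px: float,
    img_w: float,
    img_h: float,
    conf: float,
) -> Detection:
    # keep the box inside the image by nudging the centroid; ground-truth
    # motion already respects the radius margin so this only acts on jitter
    cx = min(max(cx_px, half_w_px), img_w - half_w_px)
    cy = min(max(cy_px, half_h_px), img_h - half_h_px)
    return Detection(
        frame,
        BoundingBox(cx - half_w_px, cy - half_h_px, 2 * half_w_px, 2 * half_h_px),
        conf,
    )


def render_detections(
    tracks: Sequence[GroundTruthTrack],
    noise: NoiseConfig,
    calib: PenCalibration,
    seed: int,
    *,
    bird_radius_cm: float = 8.0,
    image_width_px: float = 2592.0,
    image_height_px: float = 1944.0,
    pen_width_cm: float = 100.0,
    pen_height_cm: float = 150.0,
) -> tuple[list[FrameDetections], list[list[int]]]:
    """Corrupt ground-truth tracks into per-frame detections.

    Returns ``(frames, truth_map)`` where ``truth_map[i][j]`` is the bird id
    behind detection ``j`` of frame ``i`` (-1 for false positives).  Boxes
    have the fixed nominal size 2 * bird_radius_cm and float-pixel
    coordinates; with all noise at zero the detection centroids equal the
    ground truth exactly under the calibration round trip.
    """
    rng = np.random.default_rng(seed)
    pos = _positions_array(tracks)
    n_birds, n_frames, _ = pos.shape
    half_w = bird_radius_cm / calib.cm_per_px_x
    half_h = bird_radius_cm / calib.cm_per_px_y
    jit_x = noise.jitter_sd_cm / calib.cm_per_px_x
    jit_y = noise.jitter_sd_cm / calib.cm_per_px_y
    occl_d2 = (2.0 * bird_radius_cm) ** 2

    in_dropout = np.zeros(n_birds, dtype=bool)
    frames: list[FrameDetections] = []
    truth_map: list[list[int]] = []
    for f in range(n_frames):
        p = pos[:, f, :]
        # pairwise occlusion candidates this frame
        if noise.occlusion_dropout_prob > 0 and n_birds > 1:
            d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            occluded = (d2 < occl_d2).any(axis=1)
        else:
            occluded = np.zeros(n_birds, dtype=bool)

        dets: list[Detection] = []
        ids: list[int] = []
        for b in range(n_birds):
            if in_dropout[b]:
                if rng.random() < noise.gap_extension_prob:
                    continue
                in_dropout[b] = False
            miss = rng.random() < noise.base_miss_prob
            if not miss and occluded[b]:
                miss = rng.random() < noise.occlusion_dropout_prob
            if miss:
                in_dropout[b] = True
                continue
            cx, cy = calib.cm_to_px(p[b, 0], p[b, 1])
            if noise.jitter_sd_cm > 0:
                cx += rng.normal(0.0, jit_x)
                cy += rng.normal(0.0, jit_y)
            dets.append(
                _make_detection(f, cx, cy, half_w, half_h,
                                image_width_px, image_height_px,
                                float(rng.uniform(0.8, 1.0)))
            )
            ids.append(b)
        if noise.false_pos_rate > 0:
            for _ in range(rng.poisson(noise.false_pos_rate)):
                fx = rng.uniform(bird_radius_cm, pen_width_cm - bird_radius_cm)
                fy = rng.uniform(bird_radius_cm, pen_height_cm - bird_radius_cm)
                cx, cy = calib.cm_to_px(fx, fy)
                dets.append(
                    _make_detection(f, cx, cy, half_w, half_h,
                                    image_width_px, image_height_px,
                                    float(rng.uniform(0.3, 0.8)))
                )
                ids.append(-1)
        frames.append(FrameDetections(f, dets))
        truth_map.append(ids)
    return frames, truth_map


def inject_dropouts(
    tracks: Sequence[GroundTruthTrack],
    *,
    n_gaps: int,
    min_gap_frames: int,
    max_gap_frames: int,
    distance_threshold_cm: float,
    seed: int,
    max_tries: int = 2000,
) -> dict[int, list[tuple[int, int]]]:
    """Sample controlled occlusion-style dropout windows.

    Each window ``(start, end)`` (end exclusive) removes one bird's
    detections and is guaranteed to satisfy the re-association recovery
    regime: the bird's displacement across the window is below half the
    re-association distance threshold, and no other bird comes within the
    threshold of the bird's disappearance point for the duration of the
    window — so the reappearing bird is unambiguous.  Windows for the same
    bird are separated by at least ``max_gap_frames`` detected frames.

    Returns ``{bird_id: [(start, end), ...]}``.
    """
    rng = np.random.default_rng(seed)
    pos = _positions_array(tracks)
    n_birds, n_frames, _ = pos.shape
    thr = distance_threshold_cm
    windows: dict[int, list[tuple[int, int]]] = {b: [] for b in range(n_birds)}
    placed = 0
    for _ in range(max_tries):
        if placed >= n_gaps:
            break
        b = int(rng.integers(n_birds))
        gap = int(rng.integers(min_gap_frames, max_gap_frames + 1))
        start = int(rng.integers(max_gap_frames + 1, n_frames - gap - max_gap_frames))
        end = start + gap
        # keep windows of one bird well separated
        if any(s - max_gap_frames < end and start < e + max_gap_frames
               for s, e in windows[b]):
            continue
        disp = math.hypot(*(pos[b, end] - pos[b, start - 1]))
        if disp >= thr / 2.0:
            continue
        others = [o for o in range(n_birds) if o != b]
        if others:
            # no other bird may approach the loss or reappearance point
            # within the threshold for the window plus a max_gap margin on
            # both sides, so no temporally adjacent event is ambiguous
            lo = max(0, start - 1 - max_gap_frames)
            hi = min(n_frames, end + 1 + max_gap_frames)
            anchors = pos[b, [start - 1, end], :]  # (2, 2)
            d = np.linalg.norm(
                pos[others, lo:hi, None, :] - anchors[None, None, :, :], axis=-1
            )
            if d.min() < thr:
                continue
        windows[b].append((start, end))
        placed += 1
    return {b: sorted(w) for b, w in windows.items() if w}


def render_with_dropouts(
    tracks: Sequence[GroundTruthTrack],
    windows: dict[int, list[tuple[int, int]]],
    calib: PenCalibration,
    seed: int,
    **render_kwargs,
) -> tuple[list[FrameDetections], list[list[int]]]:
    """Render noiseless detections, then remove the frames covered by the
    injected dropout windows.  Used to study ID-switch recovery under
    controlled gap lengths."""
    frames, truth_map = render_detections(
        tracks, NoiseConfig(), calib, seed, **render_kwargs
    )
    out_frames: list[FrameDetections] = []
    out_truth: list[list[int]] = []
    for fd, ids in zip(frames, truth_map):
        keep = [
            i for i, b in enumerate(ids)
            if not any(s <= fd.frame < e for s, e in windows.get(b, []))
        ]
        out_frames.append(FrameDetections(fd.frame, [fd.detections[i] for i in keep]))
        out_truth.append([ids[i] for i in keep])
    return out_frames, out_truth


def ssl_split(
    frames: Sequence[FrameDetections], confidence_threshold: float
) -> tuple[list[FrameDetections], list[FrameDetections]]:
    """Split frames into accepted pseudo-labels and rejected frames.

    A frame is accepted when every one of its detections has confidence at
    or above the threshold — the bookkeeping step of semi-supervised
    pseudo-labeling, where only confidently labeled frames are fed back
    into training.
    """
    if not (0.0 <= confidence_threshold <= 1.0):
        raise ValueError("confidence_threshold must be in [0,1]")
    accepted, rejected = [], []
    for fd in frames:
        if all(d.confidence >= confidence_threshold for d in fd.detections):
            accepted.append(fd)
        else:
            rejected.append(fd)
    return accepted, rejected
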