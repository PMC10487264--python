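"""Mobility quantification: centroids, calibration, resampling, deadband
displacement filtering, and per-bird / flock summaries.

The displacement chain works on a merged bird trajectory: the per-frame
box centroids are resampled onto a coarse time grid (default one sample
per second, which suppresses sub-second body perturbations), consecutive
grid samples are differenced into calibrated cm step distances, steps
below the deadband are zeroed as residual body-perturbation noise, and
the surviving steps are summed into the total covered distance.  Gaps in
the trajectory are excluded, never interpolated: no step distance is
charged across a stretch with no observations, and the appearance
percentage reports separately how much of the period the bird was seen.
All public outputs are in cm and cm/s; pixels never leak past the
calibration step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BoundingBox, RunConfig
from .neo_sort import Trajectory, appearance_percentage
from .simulator import PenCalibration

__all__ = [
    "PenCalibration",
    "MobilitySummary",
    "FlockSummary",
    "centroid",
    "calibrate",
    "resample",
    "displacement_series",
    "bird_summary",
    "flock_summary",
]


@dataclass(frozen=True)
class MobilitySummary:
    """One bird's mobility over one period (e.g. an hourly recording)."""

    bird_id: int
    period: str
    total_distance_cm: float
    mean_speed_cm_s: float
    appearance_pct: float

    def __post_init__(self) -> None:
        if self.total_distance_cm < 0:
            raise ValueError("total_distance_cm must be >= 0")
        if not (0.0 <= self.appearance_pct <= 100.0 + 1e-9):
            raise ValueError("appearance_pct must be in [0, 100]")


@dataclass(frozen=True)
class FlockSummary:
    """Across-bird mean and SD of distance and speed for one period."""

    period: str
    n_birds: int
    mean_distance_cm: float
    sd_distance_cm: float
    mean_speed_cm_s: float
    sd_speed_cm_s: float


def centroid(box: BoundingBox) -> tuple[float, float]:
    """Box centroid: (x + x_width/2, y + y_height/2), in px."""
    return (box.x + box.x_width / 2.0, box.y + box.y_height / 2.0)


def calibrate(
    pen_w_cm: float, pen_h_cm: float, image_w_px: float, image_h_px: float
) -> PenCalibration:
    """Linear anisotropic px->cm calibration for a nadir camera whose
    frame the pen fills: cm_per_px = pen size / image size, per axis."""
    for name, v in (("pen_w_cm", pen_w_cm), ("pen_h_cm", pen_h_cm),
                    ("image_w_px", image_w_px), ("image_h_px", image_h_px)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return PenCalibration(pen_w_cm / image_w_px, pen_h_cm / image_h_px)


def resample(
    traj: Trajectory, interval_s: float, frame_rate: float
) -> list[tuple[float, float, float]]:
    """Keep the observation nearest each grid time t = 0, interval, 2*interval...

    An observation qualifies for a grid point only if it lies within half
    an interval of it; grid points with no qualifying observation are
    simply absent, so trajectory gaps propagate to the displacement series
    as skipped segments rather than being interpolated.  Returns
    ``(grid_time_s, x, y)`` triples (positions still in px).
    """
    if interval_s * frame_rate < 1.0:
        raise ValueError("interval_s x frame_rate must be >= 1")
    if not traj.points:
        return []
    frames = np.array([f for f, _, _ in traj.points], dtype=float)
    times = frames / frame_rate
    t_max = times[-1]
    out: list[tuple[float, float, float]] = []
    k = 0
    while True:
        t = k * interval_s
        if t > t_max + interval_s / 2.0:
            break
        i = int(np.searchsorted(times, t))
        best, best_dt = -1, interval_s / 2.0
        for cand in (i - 1, i):
            if 0 <= cand < len(times):
                dt = abs(times[cand] - t)
                if dt < best_dt or (dt == best_dt and best == -1):
                    best, best_dt = cand, dt
        if best >= 0:
            _, x, y = traj.points[best]
            out.append((t, x, y))
        k += 1
    return out


def displacement_series(
    points: Sequence[tuple[float, float, float]],
    calib: PenCalibration,
    deadband_cm: float,
    interval_s: float | None = None,
) -> list[float]:
    """Per-step calibrated distances between consecutive resampled points.

    Steps are only formed within contiguous grid runs: when
    ``interval_s`` is given, a pair of samples further apart than one
    interval (plus numerical slack) spans a gap and contributes no
    distance.  Steps shorter than ``deadband_cm`` are zeroed — they are
    read as body perturbation, not locomotion.
    """
    if deadband_cm < 0:
        raise ValueError("deadband_cm must be >= 0")
    steps: list[float] = []
    for (t0, x0, y0), (t1, x1, y1) in zip(points, points[1:]):
        if interval_s is not None and (t1 - t0) > interval_s * 1.5:
            continue
        dx = (x1 - x0) * calib.cm_per_px_x
        dy = (y1 - y0) * calib.cm_per_px_y
        d = math.hypot(dx, dy)
        steps.append(d if d >= deadband_cm else 0.0)
    return steps


def _observed_duration_s(
    points: Sequence[tuple[float, float, float]], interval_s: float
) -> float:
    """Wall-clock seconds spanned by contiguous resampled runs."""
    dur = 0.0
    for (t0, _, _), (t1, _, _) in zip(points, points[1:]):
        if (t1 - t0) <= interval_s * 1.5:
            dur += t1 - t0
    return dur


def bird_summary(
    traj: Trajectory,
    calib: PenCalibration,
    config: RunConfig,
    period: str = "",
    total_frames: int | None = None,
) -> MobilitySummary:
    """Summarize one bird's mobility over the recording.

    ``total_frames`` defaults to the last observed frame + 1 and is the
    denominator of the appearance percentage.  The speed denominator is
    the observed contiguous duration, not the wall-clock period, so a
    low-appearance bird is not biased toward zero speed.
    """
    if not traj.points:
        return MobilitySummary(traj.bird_id, period, 0.0, 0.0, 0.0)
    if total_frames is None:
        total_frames = traj.points[-1][0] + 1
    pts = resample(traj, config.sample_interval, config.frame_rate)
    steps = displacement_series(pts, calib, config.deadband,
                                config.sample_interval)
    total = float(sum(steps))
    dur = _observed_duration_s(pts, config.sample_interval)
    speed = total / dur if dur > 0 else 0.0
    return MobilitySummary(
        bird_id=traj.bird_id,
        period=period,
        total_distance_cm=total,
        mean_speed_cm_s=speed,
        appearance_pct=appearance_percentage(traj, total_frames),
    )


def flock_summary(summaries: Sequence[MobilitySummary], period: str = "") -> FlockSummary:
    """Arithmetic mean and SD across birds of distance and speed."""
    if not summaries:
        raise ValueError("flock_summary requires at least one bird summary")
    d = np.array([s.total_distance_cm for s in summaries])
    v = np.array([s.mean_speed_cm_s for s in summaries])
    return FlockSummary(
        period=period or summaries[0].period,
        n_birds=len(summaries),
        mean_distance_cm=float(d.mean()),
        sd_distance_cm=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        mean_speed_cm_s=float(v.mean()),
        sd_speed_cm_s=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
    )
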