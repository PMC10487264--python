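"""End-to-end convenience wiring: detections -> tracklets -> re-associated
bird trajectories -> mobility summaries.

Event matching is done in calibrated cm (event positions are converted
from px before thresholding) so the distance threshold means the same
thing along both pen axes even when the camera's cm-per-px differs by
axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import FrameDetections, RunConfig
from .mobility import MobilitySummary, bird_summary, calibrate
from .neo_sort import (
    BirthEvent,
    IdMapping,
    LossEvent,
    Trajectory,
    find_events,
    match_lost_new,
    merge,
)
from .simulator import PenCalibration
from .tracker import TrackerParams, Tracklet, run_tracker

__all__ = ["PipelineResult", "associate_tracklets", "run_pipeline"]


@dataclass
class PipelineResult:
    tracklets: list[Tracklet]
    mapping: IdMapping
    trajectories: list[Trajectory]
    summaries: list[MobilitySummary]
    calib: PenCalibration


def associate_tracklets(
    tracklets: Sequence[Tracklet],
    video_end: int,
    calib: PenCalibration,
    config: RunConfig,
    spawn_window: int = 3,
) -> tuple[IdMapping, list[Trajectory]]:
    """Find loss/birth events, match them with the distance threshold in
    cm, and merge the chains into bird trajectories."""
    losses, births = find_events(tracklets, video_end, spawn_window)
    losses_cm = [
        LossEvent(e.track_id, e.last_frame, calib.px_to_cm(*e.last_position))
        for e in losses
    ]
    births_cm = [
        BirthEvent(e.track_id, e.first_frame, calib.px_to_cm(*e.first_position))
        for e in births
    ]
    mapping = match_lost_new(
        losses_cm,
        births_cm,
        config.distance_threshold,
        config.max_gap,
        tracklet_lengths={t.track_id: len(t) for t in tracklets},
        min_track_length=config.min_track_length,
    )
    return mapping, merge(tracklets, mapping)


def run_pipeline(
    frames: Sequence[FrameDetections],
    config: RunConfig,
    tracker_params: TrackerParams | None = None,
) -> PipelineResult:
    """Track, re-associate and summarize a whole detection stream."""
    tracker_params = tracker_params or TrackerParams()
    calib = calibrate(
        config.pen_width_cm, config.pen_height_cm,
        config.image_width_px, config.image_height_px,
    )
    tracklets = run_tracker(frames, tracker_params)
    video_end = max((fd.frame for fd in frames), default=0)
    n_frames = video_end + 1
    mapping, trajectories = associate_tracklets(
        tracklets, video_end, calib, config,
        spawn_window=tracker_params.min_hits,
    )
    summaries = [
        bird_summary(traj, calib, config, total_frames=n_frames)
        for traj in trajectories
    ]
    return PipelineResult(tracklets, mapping, trajectories, summaries, calib)
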