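"""Lost-ID / new-ID re-association and track merging.

When a bird is occluded for longer than the tracker's ``max_age`` the
tracker retires its ID and assigns a fresh one on reappearance, so one
bird ends up owning several tracklets.  This module repairs that: it
collects the loss events (tracklets ending before the video does) and
birth events (tracklets born after the initial spawn cohort), pairs them
by positional proximity — a loss and a birth closer than a distance
threshold within a bounded temporal gap are the same bird — merges the
paired histories into bird-level trajectories, and deletes unmatched
short-lived new tracks as false detections.

Conflicts are resolved globally: over all candidate (loss, birth) pairs a
maximum-cardinality, minimum-total-distance one-to-one matching is taken,
so two reappearing birds cannot claim the same lost ID.  Chains compose
transitively (A lost -> B, B lost -> C collapses onto root A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import BoundingBox
from .tracker import Tracklet

__all__ = [
    "LossEvent",
    "BirthEvent",
    "IdMapping",
    "Trajectory",
    "find_events",
    "match_lost_new",
    "merge",
    "appearance_percentage",
    "threshold_sweep",
]


@dataclass(frozen=True)
class LossEvent:
    """A tracklet's disappearance: its final observation."""

    track_id: int
    last_frame: int
    last_position: tuple[float, float]


@dataclass(frozen=True)
class BirthEvent:
    """A tracklet's appearance after the initial spawn cohort."""

    track_id: int
    first_frame: int
    first_position: tuple[float, float]


@dataclass
class IdMapping:
    """Result of lost/new association.

    ``merges`` maps each new (child) id to the lost (parent) id it was
    identified with; chains are resolved to their root via
    :meth:`resolve`.  ``deletions`` are false-detection track ids;
    ``unresolved`` are events left unmatched.
    """

    merges: dict[int, int] = field(default_factory=dict)
    deletions: set[int] = field(default_factory=set)
    unresolved: set[int] = field(default_factory=set)

    def resolve(self, track_id: int) -> int:
        """Follow the merge chain to its root id."""
        seen = set()
        while track_id in self.merges:
            if track_id in seen:
                raise ValueError(f"cyclic merge chain at id {track_id}")
            seen.add(track_id)
            track_id = self.merges[track_id]
        return track_id


@dataclass
class Trajectory:
    """Bird-level merged centroid time series, in pixels.

    ``bird_id`` is the root (earliest) tracker id of the merge chain;
    ``points`` are (frame, x, y); ``boxes`` align with points and carry
    the underlying detections for round-tripping to MOT files.
    """

    bird_id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)
    source_ids: list[int] = field(default_factory=list)
    boxes: list[BoundingBox] | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> list[int]:
        return [f for f, _, _ in self.points]


def find_events(
    tracklets: Sequence[Tracklet],
    video_end: int,
    spawn_window: int = 3,
) -> tuple[list[LossEvent], list[BirthEvent]]:
    """Extract loss and birth events from a finished tracking run.

    Every tracklet ending before ``video_end`` (the last frame index of
    the video) emits a loss at its final observation.  Every tracklet born
    after the initial spawn cohort — tracks whose first observation lies
    in the first ``spawn_window`` frames — emits a birth at its first
    observation.
    """
    losses = [
        LossEvent(t.track_id, t.observations[-1][0], t.last_position)
        for t in tracklets
        if t.observations[-1][0] < video_end
    ]
    births = [
        BirthEvent(t.track_id, t.first_frame, t.first_position)
        for t in tracklets
        if t.first_frame >= spawn_window
    ]
    return losses, births


_BIG = 1e12  # forbidden-pair cost; dominates any realistic distance sum


def match_lost_new(
    losses: Sequence[LossEvent],
    births: Sequence[BirthEvent],
    distance_threshold: float,
    max_gap: int,
    *,
    tracklet_lengths: dict[int, int] | None = None,
    min_track_length: int = 1,
) -> IdMapping:
    """Associate lost IDs with new IDs by positional distance.

    A (loss, birth) pair is a candidate when the birth follows the loss by
    at most ``max_gap`` frames and their positions are closer than
    ``distance_threshold`` (same units as the event positions).  Over all
    candidates a maximum-cardinality minimum-total-distance one-to-one
    matching is taken; ties broken toward earlier birth frames.  Matched
    births become merges (child -> parent).  Unmatched births whose
    tracklet is shorter than ``min_track_length`` observations are deleted
    as false detections; all other unmatched events are left unresolved.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    births = sorted(births, key=lambda b: (b.first_frame, b.track_id))
    mapping = IdMapping()
    matched_births: set[int] = set()
    if losses and births:
        cost = np.full((len(losses), len(births)), _BIG)
        for i, lo in enumerate(losses):
            for j, bi in enumerate(births):
                if lo.track_id == bi.track_id:
                    continue
                gap = bi.first_frame - lo.last_frame
                if not (0 < gap <= max_gap):
                    continue
                d = math.hypot(
                    lo.last_position[0] - bi.first_position[0],
                    lo.last_position[1] - bi.first_position[1],
                )
                if d < distance_threshold:
                    # tiny frame-ordered epsilon implements the tie-break
                    cost[i, j] = d + 1e-9 * j
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < _BIG:
                mapping.merges[births[j].track_id] = losses[i].track_id
                matched_births.add(births[j].track_id)
    for bi in births:
        if bi.track_id in matched_births:
            continue
        if (
            tracklet_lengths is not None
            and tracklet_lengths.get(bi.track_id, min_track_length) < min_track_length
        ):
            mapping.deletions.add(bi.track_id)
        else:
            mapping.unresolved.add(bi.track_id)
    for lo in losses:
        if lo.track_id not in mapping.merges.values():
            mapping.unresolved.add(lo.track_id)
    # ids that are merge sources should not linger in unresolved
    mapping.unresolved -= set(mapping.merges.keys())
    return mapping


def merge(tracklets: Sequence[Tracklet], mapping: IdMapping) -> list[Trajectory]:
    """Concatenate merge chains into bird-level trajectories.

    Each chain's tracklets are concatenated time-sorted under the chain's
    root id; deleted tracklets are dropped; every other tracklet becomes a
    singleton trajectory.  Raises if two chain members overlap in frame
    range (a mapping-integrity violation).
    """
    groups: dict[int, list[Tracklet]] = {}
    for t in tracklets:
        if t.track_id in mapping.deletions:
            continue
        groups.setdefault(mapping.resolve(t.track_id), []).append(t)
    out: list[Trajectory] = []
    for root, members in sorted(groups.items()):
        members.sort(key=lambda t: t.first_frame)
        points: list[tuple[int, float, float]] = []
        boxes: list[BoundingBox] = []
        last_frame = -1
        for t in members:
            if t.first_frame <= last_frame:
                raise ValueError(
                    f"merge chain for root {root}: tracklet {t.track_id} "
                    f"overlaps previous member in frame range"
                )
            for frame, box, (cx, cy) in t.observations:
                points.append((frame, cx, cy))
                boxes.append(box)
            last_frame = t.observations[-1][0]
        out.append(
            Trajectory(
                bird_id=root,
                points=points,
                source_ids=[t.track_id for t in members],
                boxes=boxes,
            )
        )
    return out


def appearance_percentage(traj: Trajectory, total_frames: int) -> float:
    """Percent of video frames in which the bird has an observation."""
    if total_frames < 1:
        raise ValueError("total_frames must be >= 1")
    return 100.0 * len({f for f, _, _ in traj.points}) / total_frames


def threshold_sweep(
    losses: Sequence[LossEvent],
    births: Sequence[BirthEvent],
    thresholds: Sequence[float],
    max_gap: int,
) -> list[tuple[float, int]]:
    """Merge count as a function of the distance threshold.

    The reference procedure selects the threshold by trial and error; this
    utility exposes the merges-vs-threshold curve so the knee can be read
    off (plot with :func:`broilertrack.cli.plot_sweep` or any tool).
    """
    out = []
    for thr in thresholds:
        m = match_lost_new(losses, births, thr, max_gap)
        out.append((float(thr), len(m.merges)))
    return out
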