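"""Online multi-object tracker: constant-velocity Kalman filter plus
Hungarian assignment, with a tentative/confirmed/lost track lifecycle.

This is the classic kinematic core of deep-sort-style tracking.  The state
is the 8-vector (cx, cy, w, h, vx, vy, vw, vh) — box centroid, box size and
their per-frame velocities.  Assignment cost is the Euclidean distance
between the predicted track centroid and the detection centroid, gated at
``gate_distance``; an optional appearance-cost hook can add a descriptor
term but is off by default.  ID switches caused by occlusion gaps longer
than ``max_age`` are deliberately left in the output — repairing them is
the job of the re-association layer (:mod:`broilertrack.neo_sort`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_formats import BoundingBox, Detection, FrameDetections

__all__ = [
    "KalmanState",
    "Tracklet",
    "TrackerParams",
    "TrackerState",
    "TrackStatus",
    "kf_init",
    "kf_predict",
    "kf_update",
    "associate",
    "step",
    "run_tracker",
]

# constant-velocity transition and measurement matrices for the 8-state model
_DIM = 8
_F = np.eye(_DIM)
_F[:4, 4:] = np.eye(4)
_H = np.zeros((4, _DIM))
_H[:4, :4] = np.eye(4)


class TrackStatus(str, Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    LOST = "lost"


@dataclass(frozen=True)
class KalmanState:
    """Gaussian belief over (cx, cy, w, h, vx, vy, vw, vh)."""

    mean: np.ndarray  # (8,)
    covariance: np.ndarray  # (8, 8)

    def __post_init__(self) -> None:
        if self.mean.shape != (_DIM,) or self.covariance.shape != (_DIM, _DIM):
            raise ValueError("KalmanState must be 8-dimensional")


@dataclass(frozen=True)
class TrackerParams:
    """Tracker hyper-parameters.

    ``gate_distance`` is the assignment cost cutoff in px; ``max_age`` is
    how many consecutive unmatched frames a confirmed track survives;
    ``min_hits`` consecutive matches confirm a tentative track.  Noise
    scales are in px: ``process_noise_scale`` is the per-frame positional
    process SD and ``measurement_noise_scale`` the detection centroid SD.
    """

    gate_distance: float = 200.0
    max_age: int = 30
    min_hits: int = 3
    process_noise_scale: float = 1.0
    measurement_noise_scale: float = 1.0
    appearance_cost: Callable[[object, Detection], float] | None = None
    appearance_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.max_age < 1 or self.min_hits < 1 or self.gate_distance <= 0:
            raise ValueError("invalid tracker parameters")


def _noise_matrices(params: TrackerParams) -> tuple[np.ndarray, np.ndarray]:
    q = params.process_noise_scale
    Q = np.diag([q**2] * 4 + [(q / 2.0) ** 2] * 4)
    r = params.measurement_noise_scale
    R = np.eye(4) * r**2
    return Q, R


def kf_init(det: Detection, params: TrackerParams) -> KalmanState:
    """Initialize a track state from a first detection: measured position
    and size, zero velocity with a wide velocity prior."""
    cx, cy = det.box.centroid
    mean = np.array(
        [cx, cy, det.box.x_width, det.box.y_height, 0.0, 0.0, 0.0, 0.0]
    )
    r = params.measurement_noise_scale
    cov = np.diag([r**2] * 4 + [1e4 * max(r, 1.0) ** 2] * 4)
    return KalmanState(mean, cov)


def kf_predict(state: KalmanState, params: TrackerParams) -> KalmanState:
    """Advance the belief one frame under the constant-velocity model."""
    Q, _ = _noise_matrices(params)
    mean = _F @ state.mean
    cov = _F @ state.covariance @ _F.T + Q
    return KalmanState(mean, cov)


def kf_update(state: KalmanState, det: Detection, params: TrackerParams) -> KalmanState:
    """Standard linear Kalman measurement update on (cx, cy, w, h)."""
    cx, cy = det.box.centroid
    z = np.array([cx, cy, det.box.x_width, det.box.y_height])
    if not np.all(np.isfinite(z)):
        raise FloatingPointError(f"non-finite measurement {z}")
    _, R = _noise_matrices(params)
    S = _H @ state.covariance @ _H.T + R
    K = state.covariance @ _H.T @ np.linalg.solve(S, np.eye(4))
    innovation = z - _H @ state.mean
    mean = state.mean + K @ innovation
    I_KH = np.eye(_DIM) - K @ _H
    # Joseph form keeps the covariance symmetric PSD
    cov = I_KH @ state.covariance @ I_KH.T + K @ R @ K.T
    mean[2] = max(mean[2], 1e-6)
    mean[3] = max(mean[3], 1e-6)
    return KalmanState(mean, cov)


@dataclass
class Tracklet:
    """One tracker ID's contiguous observation sequence."""

    track_id: int
    observations: list[tuple[int, BoundingBox, tuple[float, float]]] = field(
        default_factory=list
    )
    state: KalmanState | None = None
    status: TrackStatus = TrackStatus.TENTATIVE
    last_frame: int = -1
    hit_streak: int = 0
    miss_count: int = 0
    ever_confirmed: bool = False

    @property
    def first_frame(self) -> int:
        return self.observations[0][0]

    @property
    def first_position(self) -> tuple[float, float]:
        return self.observations[0][2]

    @property
    def last_position(self) -> tuple[float, float]:
        return self.observations[-1][2]

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class TrackerState:
    """Mutable whole-tracker state threaded through :func:`step`."""

    params: TrackerParams
    live: list[Tracklet] = field(default_factory=list)
    finished: list[Tracklet] = field(default_factory=list)
    next_id: int = 1
    last_frame: int = -1


def associate(
    tracks: Sequence[Tracklet],
    dets: Sequence[Detection],
    params: TrackerParams,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimally assign detections to predicted track positions.

    Returns ``(matches, unmatched_track_idx, unmatched_det_idx)`` where
    matches are (track_index, det_index) pairs.  The assignment minimizes
    total centroid distance (Hungarian algorithm); any assigned pair whose
    cost exceeds ``gate_distance`` is dissolved into unmatched on both
    sides.
    """
    if not tracks or not dets:
        return [], list(range(len(tracks))), list(range(len(dets)))
    cost = np.empty((len(tracks), len(dets)))
    for i, trk in enumerate(tracks):
        px, py = trk.state.mean[0], trk.state.mean[1]
        for j, det in enumerate(dets):
            cx, cy = det.box.centroid
            c = float(np.hypot(px - cx, py - cy))
            if params.appearance_cost is not None and params.appearance_weight > 0:
                c = (1 - params.appearance_weight) * c + (
                    params.appearance_weight * params.appearance_cost(trk, det)
                )
            cost[i, j] = c
    # gate inside the assignment: all over-gate entries share one large
    # constant, so the solver first maximizes the number of feasible
    # matches and then minimizes their total cost; solving on the raw
    # matrix and gating afterwards can sacrifice perfect matches to
    # cheapen a forced infeasible edge
    feasible = cost <= params.gate_distance
    big = 1e9
    gated = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(gated)
    matches: list[tuple[int, int]] = []
    unmatched_t = set(range(len(tracks)))
    unmatched_d = set(range(len(dets)))
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            matches.append((int(i), int(j)))
            unmatched_t.discard(int(i))
            unmatched_d.discard(int(j))
    return matches, sorted(unmatched_t), sorted(unmatched_d)


def step(
    state: TrackerState, frame_dets: FrameDetections, params: TrackerParams | None = None
) -> TrackerState:
    """Advance the tracker by one frame (mutates and returns ``state``).

    Predict all live tracks, associate, update matched tracks, spawn
    tentative tracks from unmatched detections (fresh monotone IDs), age
    unmatched tracks and retire those exceeding ``max_age`` misses.
    Tentative tracks are dropped on their first miss; they are confirmed
    after ``min_hits`` consecutive matches.
    """
    params = params or state.params
    frame = frame_dets.frame
    if frame <= state.last_frame:
        raise ValueError(
            f"frames must be presented in increasing order "
            f"(got {frame} after {state.last_frame})"
        )
    state.last_frame = frame

    for trk in state.live:
        trk.state = kf_predict(trk.state, params)

    dets = frame_dets.detections
    matches, um_tracks, um_dets = associate(state.live, dets, params)

    for ti, dj in matches:
        trk = state.live[ti]
        det = dets[dj]
        trk.state = kf_update(trk.state, det, params)
        trk.observations.append((frame, det.box, det.box.centroid))
        trk.last_frame = frame
        trk.hit_streak += 1
        trk.miss_count = 0
        if trk.status is TrackStatus.TENTATIVE and trk.hit_streak >= params.min_hits:
            trk.status = TrackStatus.CONFIRMED
            trk.ever_confirmed = True

    still_live: list[Tracklet] = [state.live[ti] for ti, _ in matches]
    for ti in um_tracks:
        trk = state.live[ti]
        trk.hit_streak = 0
        trk.miss_count += 1
        if trk.status is TrackStatus.TENTATIVE:
            # unconfirmed track lost before min_hits: discard silently
            continue
        if trk.miss_count > params.max_age:
            trk.status = TrackStatus.LOST
            state.finished.append(trk)
        else:
            still_live.append(trk)

    for dj in um_dets:
        det = dets[dj]
        trk = Tracklet(
            track_id=state.next_id,
            observations=[(frame, det.box, det.box.centroid)],
            state=kf_update(kf_init(det, params), det, params),
            status=TrackStatus.CONFIRMED if params.min_hits == 1 else TrackStatus.TENTATIVE,
            last_frame=frame,
            hit_streak=1,
        )
        if params.min_hits == 1:
            trk.ever_confirmed = True
        state.next_id += 1
        still_live.append(trk)

    still_live.sort(key=lambda t: t.track_id)
    state.live = still_live
    return state


def run_tracker(
    frames: Sequence[FrameDetections], params: TrackerParams | None = None
) -> list[Tracklet]:
    """Track a whole detection stream and return every tracklet that was
    ever confirmed, including those terminated mid-video, sorted by id."""
    params = params or TrackerParams()
    state = TrackerState(params=params)
    for fd in frames:
        step(state, fd, params)
    out = state.finished + [t for t in state.live if t.ever_confirmed]
    out.sort(key=lambda t: t.track_id)
    return out
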