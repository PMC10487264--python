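"""Detection and tracking quality metrics.

Detection scoring follows the standard object-detection protocol: greedy
confidence-descending IoU matching against ground-truth boxes yields
true/false positive counts, precision = TP / (TP + FP), and average
precision is the area under the all-point-interpolated precision–recall
curve.  With a single object class the mean average precision equals the
AP.  The coefficient of determination R² uses the standard
squared-residual form 1 - SS_res / SS_tot.

Tracking quality against simulator ground truth is measured by
``id_recovery_metrics``: the fraction of attempted lost/new merges that
join two tracklets of the same true bird, and the mean relative error of
recovered per-bird distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import BoundingBox, FrameDetections
from .neo_sort import IdMapping, Trajectory
from .simulator import GroundTruthTrack, PenCalibration
from .tracker import Tracklet

__all__ = [
    "DetectionMatchResult",
    "MetricReport",
    "iou",
    "truth_boxes",
    "match_detections",
    "precision",
    "average_precision",
    "r_squared",
    "tracklet_truth_ids",
    "id_recovery_metrics",
]


@dataclass(frozen=True)
class DetectionMatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    iou_threshold: float

    def __post_init__(self) -> None:
        if min(self.true_positives, self.false_positives, self.false_negatives) < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class MetricReport:
    precision: float
    ap_per_class: tuple[float, ...]
    map: float
    r_squared: float | None = None


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes."""
    ix = max(0.0, min(a.x + a.x_width, b.x + b.x_width) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.y_height, b.y + b.y_height) - max(a.y, b.y))
    inter = ix * iy
    union = a.x_width * a.y_height + b.x_width * b.y_height - inter
    return inter / union if union > 0 else 0.0


def truth_boxes(
    truth: Sequence[GroundTruthTrack],
    calib: PenCalibration,
    bird_radius_cm: float,
) -> dict[int, list[BoundingBox]]:
    """Render ground-truth tracks to per-frame boxes of the simulator's
    nominal size (2 * bird_radius_cm per side, in px)."""
    half_w = bird_radius_cm / calib.cm_per_px_x
    half_h = bird_radius_cm / calib.cm_per_px_y
    out: dict[int, list[BoundingBox]] = {}
    for t in truth:
        for frame, x_cm, y_cm in t.positions:
            cx, cy = calib.cm_to_px(x_cm, y_cm)
            out.setdefault(frame, []).append(
                BoundingBox(max(cx - half_w, 0.0), max(cy - half_h, 0.0),
                            2 * half_w, 2 * half_h)
            )
    return out


def _label_detections(
    dets: Sequence[FrameDetections],
    gt: Mapping[int, Sequence[BoundingBox]],
    iou_threshold: float,
) -> tuple[list[tuple[float, bool]], int]:
    """Greedy confidence-descending matching.

    Returns ``(labels, n_truth)`` where labels are (confidence, is_tp)
    per detection.  Within each frame, detections are processed in
    descending confidence; each claims the unmatched truth box of highest
    IoU if that IoU reaches the threshold.
    """
    labels: list[tuple[float, bool]] = []
    n_truth = sum(len(v) for v in gt.values())
    for fd in dets:
        boxes = list(gt.get(fd.frame, []))
        used = [False] * len(boxes)
        order = sorted(range(len(fd.detections)),
                       key=lambda i: -fd.detections[i].confidence)
        for i in order:
            det = fd.detections[i]
            best_j, best_iou = -1, iou_threshold
            for j, tb in enumerate(boxes):
                if used[j]:
                    continue
                v = iou(det.box, tb)
                if v >= best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                used[best_j] = True
                labels.append((det.confidence, True))
            else:
                labels.append((det.confidence, False))
    return labels, n_truth


def match_detections(
    dets: Sequence[FrameDetections],
    truth: Sequence[GroundTruthTrack],
    calib: PenCalibration,
    iou_threshold: float = 0.5,
    *,
    bird_radius_cm: float = 8.0,
) -> DetectionMatchResult:
    """Count TP/FP/FN of a detection stream against ground-truth tracks."""
    gt = truth_boxes(truth, calib, bird_radius_cm)
    labels, n_truth = _label_detections(dets, gt, iou_threshold)
    tp = sum(1 for _, ok in labels if ok)
    fp = len(labels) - tp
    return DetectionMatchResult(tp, fp, n_truth - tp, iou_threshold)


def precision(result: DetectionMatchResult) -> float:
    """TP / (TP + FP); defined as 1.0 when there are no predictions."""
    denom = result.true_positives + result.false_positives
    return result.true_positives / denom if denom > 0 else 1.0


def average_precision(
    dets: Sequence[FrameDetections],
    truth: Sequence[GroundTruthTrack],
    calib: PenCalibration,
    iou_threshold: float = 0.5,
    *,
    bird_radius_cm: float = 8.0,
) -> MetricReport:
    """AP under the all-point-interpolated PR curve; mAP = AP (one class).

    Detections are ranked by confidence across the whole stream; the
    precision envelope is integrated over recall (the continuous
    interpolation, not the 11-point variant).
    """
    gt = truth_boxes(truth, calib, bird_radius_cm)
    labels, n_truth = _label_detections(dets, gt, iou_threshold)
    if n_truth == 0:
        raise ValueError("average_precision undefined with empty ground truth")
    if not labels:
        report_p = 1.0
        return MetricReport(report_p, (0.0,), 0.0)
    labels.sort(key=lambda t: -t[0])
    tp_cum = np.cumsum([1.0 if ok else 0.0 for _, ok in labels])
    fp_cum = np.cumsum([0.0 if ok else 1.0 for _, ok in labels])
    recall = tp_cum / n_truth
    prec = tp_cum / (tp_cum + fp_cum)
    # precision envelope (monotone non-increasing from the right)
    env = np.maximum.accumulate(prec[::-1])[::-1]
    r = np.concatenate([[0.0], recall])
    ap = float(np.sum((r[1:] - r[:-1]) * env))
    overall_p = float(prec[-1])
    return MetricReport(overall_p, (ap,), ap)


def r_squared(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(actual, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("sequences must have equal length >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for constant actual values")
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _det_key(frame: int, box: BoundingBox) -> tuple:
    return (frame, round(box.x, 6), round(box.y, 6),
            round(box.x_width, 6), round(box.y_height, 6))


def tracklet_truth_ids(
    tracklets: Sequence[Tracklet],
    det_frames: Sequence[FrameDetections],
    truth_map: Sequence[Sequence[int]],
) -> dict[int, int]:
    """Majority true bird id per tracklet (-1 for mostly-false tracks).

    Observations are joined back to the rendered detections by exact
    (frame, box) identity, which the tracker preserves.
    """
    lookup: dict[tuple, int] = {}
    for fd, ids in zip(det_frames, truth_map):
        for det, bid in zip(fd.detections, ids):
            lookup[_det_key(fd.frame, det.box)] = bid
    out: dict[int, int] = {}
    for t in tracklets:
        votes: dict[int, int] = {}
        for frame, box, _ in t.observations:
            bid = lookup.get(_det_key(frame, box))
            if bid is not None:
                votes[bid] = votes.get(bid, 0) + 1
        out[t.track_id] = max(votes, key=votes.get) if votes else -1
    return out


def id_recovery_metrics(
    tracklets: Sequence[Tracklet],
    mapping: IdMapping,
    trajectories: Sequence[Trajectory],
    det_frames: Sequence[FrameDetections],
    truth_map: Sequence[Sequence[int]],
    truth: Sequence[GroundTruthTrack],
    calib: PenCalibration,
    config,
) -> tuple[float, float]:
    """Score re-association against simulator ground truth.

    Returns ``(merge_accuracy, distance_error)``: the fraction of merges
    joining two tracklets whose majority true ids agree (1.0 when no
    merge was attempted), and the mean relative per-bird error between the
    recovered total distance and the ground-truth path length sampled on
    the same time grid with the same deadband.
    """
    from .mobility import bird_summary, displacement_series, resample

    tid2bird = tracklet_truth_ids(tracklets, det_frames, truth_map)
    if mapping.merges:
        correct = sum(
            1 for child, parent in mapping.merges.items()
            if tid2bird.get(child) == tid2bird.get(parent) != -1
        )
        merge_accuracy = correct / len(mapping.merges)
    else:
        merge_accuracy = 1.0

    n_frames = len(det_frames)
    # truth distance on the same sampling grid and deadband as the
    # recovered trajectories; positions are already cm, so identity calib
    unit = PenCalibration(1.0, 1.0)
    truth_dist = {}
    for t in truth:
        gt_traj = Trajectory(bird_id=t.bird_id,
                             points=[(f, x, y) for f, x, y in t.positions])
        pts = resample(gt_traj, config.sample_interval, config.frame_rate)
        steps = displacement_series(pts, unit, config.deadband,
                                    config.sample_interval)
        truth_dist[t.bird_id] = float(sum(steps))

    errors = []
    for traj in trajectories:
        majority = tid2bird.get(traj.source_ids[0], -1)
        if majority < 0 or majority not in truth_dist:
            continue
        s = bird_summary(traj, calib, config, total_frames=n_frames)
        td = truth_dist[majority]
        if td > 0:
            errors.append(abs(s.total_distance_cm - td) / td)
    distance_error = float(np.mean(errors)) if errors else 0.0
    return merge_accuracy, distance_error
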