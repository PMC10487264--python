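# Methods

## Problem and scope

`broilertrack` quantifies the mobility of individual broilers (meat
chickens) filmed by a fixed nadir camera over a small pen. The detector
itself (a trained CNN emitting per-frame bounding boxes) is outside the
package; the input is its output — per-frame boxes with confidences — and
the output is per-bird and flock-level covered distance, mean speed, and
appearance percentage. Between the two sit three stages:

1. **Kinematic tracking** (`tracker`): an online constant-velocity Kalman
   filter per track plus Hungarian assignment of detections to predicted
   track positions, with the classic tentative/confirmed/lost lifecycle.
2. **Lost-ID / new-ID re-association** (`neo_sort`): a post-hoc repair
   pass. When a bird is occluded longer than the tracker's patience
   (`max_age`), the tracker retires its ID and issues a fresh one on
   reappearance; re-association pairs each loss event with a temporally
   and spatially compatible birth event and merges the track fragments
   into one bird-level trajectory. Unmatched short-lived new tracks are
   deleted as false detections.
3. **Mobility quantification** (`mobility`): box centroids
   ((x + w/2, y + h/2)), linear px→cm calibration, resampling onto a 1-s
   grid, deadband filtering of sub-locomotion jitter, and summation of
   the surviving step distances.

Because real pen video cannot ship with the package, a synthetic pen
simulator (`simulator`) generates ground-truth trajectories and corrupts
them into realistic detection streams; every stage is validated against
that ground truth.

## Tracking model

Track state is the 8-vector (cx, cy, w, h, vx, vy, vw, vh) in px and
px/frame, the standard deep-sort parameterization (box-size velocities are
carried for forward compatibility; only the centroid enters the
assignment cost). Transition is constant-velocity; process noise is
diagonal with positional SD `process_noise_scale` (default 1 px/frame)
and velocity SD half that; measurement noise is diagonal with SD
`measurement_noise_scale` (default 1 px). New tracks start at the
measured box with zero velocity and a wide velocity prior (variance 1e4),
so velocity estimates converge within a handful of frames; on exact
constant-velocity input the velocity error is below 1e-6 after 20 frames.
The measurement update uses the Joseph-form covariance update for
numerical symmetry.

Assignment cost is the Euclidean distance between predicted and measured
centroid. Distance, not IoU, is the default because the birds are small
relative to the pen and the re-association rule downstream is also
distance-based; an appearance-descriptor hook (`appearance_cost`,
`appearance_weight`) can blend in an external embedding but is off by
default — the original deep-sort appearance CNN needs a GPU and training
data and is out of scope. Gating happens *inside* the optimal assignment:
entries above `gate_distance` are set to one shared large constant before
the Hungarian solve. Solving on the raw matrix and discarding over-gate
pairs afterwards is subtly wrong — on a square cost matrix the solver
must place every row somewhere, and it can lower the total by breaking a
perfect match to cheapen a forced infeasible edge; with the shared
constant it instead maximizes the number of feasible matches, then
minimizes their cost.

Lifecycle defaults: `min_hits` = 3 consecutive matches to confirm,
`max_age` = 30 frames of misses before retirement, tentative tracks are
dropped on their first miss. Track IDs increase monotonically and are
never reused.

## Re-association rule

After tracking, every tracklet ending before the video does emits a loss
event at its last observation; every tracklet born after the initial
spawn cohort (tracks appearing within the first `min_hits` frames) emits
a birth event. A (loss, birth) pair is a candidate when the birth follows
the loss by at most `max_gap` frames and the event positions are closer
than `distance_threshold`. Over all candidates a maximum-cardinality,
minimum-total-distance one-to-one matching is taken (ties broken toward
earlier births); matched pairs become child→parent merges, chains
compose transitively onto the earliest (root) ID, and a bird may absorb
several new IDs sequentially through such chains. Matching is done
offline over the whole recording: it is strictly more informed than an
online variant and exactly reproducible.

Choices the procedure leaves open, fixed here:

- **Conflict resolution.** "Closer than the threshold means the same
  bird" is ambiguous when several events are mutually close; the global
  minimum-distance matching resolves conflicts with the same philosophy
  as the tracker's own assignment. The matching uses the same
  feasible-edge padding as the tracker, which also makes the merge count
  non-decreasing in the threshold (the candidate edge set only grows).
- **Units.** The pipeline converts event positions to cm before matching
  so the threshold means the same thing along both pen axes even though
  the camera's cm-per-px differs by axis. The threshold itself is
  config-exposed (default 30 cm ≈ two body diameters); the reference
  procedure chose it by trial and error, and `threshold_sweep` (CLI
  `sweep`) tabulates merges vs threshold so the knee can be read off.
- **Temporal window.** `max_gap` defaults to 10 s of frames.
- **Deletion rule.** "Delete falsely detected instances" is made precise
  as: an unmatched *new* track shorter than `min_track_length`
  observations (default 5) is deleted; everything else is kept as an
  unresolved singleton trajectory.

Merging concatenates chain members time-sorted and refuses overlapping
frame ranges (a mapping-integrity violation). Observations are conserved:
nothing is duplicated, and only the deletion rule drops anything.

## Mobility quantification

Displacements are computed between observations "separated by 1 s"
(`sample_interval`, default 1.0 s): the observation nearest each grid
time within half an interval is kept; empty grid points stay empty. Gaps
are **excluded, not interpolated** — no step is charged across a gap, and
the appearance percentage (observed frames / total frames) reports
coverage separately; interpolating would invent distance for hidden
birds. Consecutive grid steps are converted to cm with the anisotropic
calibration (cm_per_px = pen size / image size per axis; nadir view, no
lens-distortion model) and steps below `deadband` (default 0.5 cm — the
reference procedure acknowledges such a calibration without giving a
value) are zeroed as body perturbation rather than locomotion. Mean
speed divides total distance by the *observed contiguous* duration, not
the wall-clock period, so low-appearance birds are not biased toward
zero speed. Flock summaries are the across-bird mean and SD (ddof=1).

Useful consequences, verified as properties: total distance is
non-increasing in the deadband and (on nested grids) in the sampling
interval, and coarser sampling never measures more than the full-rate
polyline length (triangle inequality).

## Synthetic pen and what it does (not) emulate

The generator's defaults reproduce the reference recording conditions: a
100 cm × 150 cm pen imaged at 2592 × 1944 px, 12 birds (16 for the
denser pen), 15-min recordings. The frame rate is set to 5 fps — high
enough that per-frame displacements (~1 cm) are far below bird spacing,
low enough to keep simulations cheap; all analyses resample to 1 s
anyway, so the tracker, not the mobility figures, is what the frame rate
exercises.

Motion is a pause-and-travel waypoint walk: each frame a bird rests with
probability `pause_prob` (default 0.5; resting adds a sub-deadband
perturbation of SD 0.004·mean_speed) or walks toward a uniformly drawn
waypoint at speed ~ Normal(5, 1) cm/s, reflected at walls (inset by the
body radius so a rendered box never leaves the image). Birds are solid:
a move bringing two centers closer than `min_separation_cm` (default one
body radius, 8 cm) is blocked and the waypoint redrawn. The separation
constraint is essential for the package's own validation — with zero
rendering noise, two birds gliding over each other produce literally
identical detections and *no* kinematic tracker could keep their
identities; solid bodies make the noiseless limit well-posed. The
expected path length under this law is
(1 − pause_prob)·mean_speed·duration, which the tests verify by Monte
Carlo. Bodies may still overlap visually (separation < one diameter),
which is exactly the regime that triggers occlusion dropouts.

Detection corruption: per frame and bird, a base miss (`base_miss_prob`)
or, when overlapping another bird, an occlusion dropout
(`occlusion_dropout_prob`); an active dropout persists with
`gap_extension_prob`, producing the multi-frame gaps that break tracker
IDs. Detected boxes have a fixed nominal size (2·bird_radius per side;
growth across rearing days is modeled by changing `bird_radius_cm`
between runs), centroid jitter of SD `jitter_sd_cm`, and confidences
drawn in [0.8, 1.0]; false positives arrive as Poisson(`false_pos_rate`)
per frame, uniform over the pen, with confidences in [0.3, 0.8]. The
reference study reports no miss/false rates for its detector, so these
magnitudes are free parameters; the test suite's noisy regimes
(base_miss 0.25 giving ~9 of 12 detected) mirror its reported detection
means only qualitatively.

Not emulated: photorealism, behavior (feeding/drinking), growth within a
run, camera distortion, detector confidence calibration. Passing tests
therefore demonstrate the correctness of the tracking/association/
mobility machinery under controlled corruption — not detector quality on
real video.

`inject_dropouts` generates *controlled* occlusion windows for studying
ID-switch recovery: windows are rejection-sampled until the bird's
displacement across the window is below half the re-association
threshold and no other bird approaches the loss/reappearance points
within the threshold for the window ± `max_gap`. Under those conditions
the reappearing bird is unambiguous and recovery should be exact; without
the isolation condition, two birds reappearing near each other can be
swapped by a perfectly rational minimum-distance matching, which is an
ambiguity of the rule, not an implementation defect.

## Detection metrics

Greedy confidence-descending IoU matching (threshold default 0.5)
against ground-truth boxes gives TP/FP/FN; precision = TP/(TP+FP),
defined as 1.0 with no predictions. Average precision integrates the
all-point-interpolated precision–recall envelope (the continuous
integral, not the 11-point variant — the detector framework the
reference used does not say which it computed, and the continuous form
is the modern default); with one object class, mAP = AP identically.
R² is implemented in the standard squared-residual form
1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)²; it errors on constant actuals rather than
returning a conventional value.

## Numerical and degenerate-input choices

- Boxes are float-pixel; MOT files are 1-based on disk, 0-based in
  memory; integer-pixel boxes round-trip bit-exactly through the writer.
- The coordinate convention is minimum-corner (left, top, width,
  height): the centroid formula x + w/2 forces it.
- Invalid detector rows (non-positive sizes, out-of-range values) are
  skipped and counted, not fatal; structurally unparseable rows raise
  with the line number.
- Resampling keeps a trailing grid point whenever an observation lies
  within half an interval of it, so recordings whose length is not an
  exact multiple of the interval do not silently lose their tail.
- An empty trajectory summarizes to zero distance/speed and 0%
  appearance; an empty flock is an error.
- Simulation sizes in the test suite are 120–900 s at 5 fps with 12
  birds, chosen so the full suite and the acceptance script each run in
  a couple of minutes on one core.

## Known limitations

- Re-association is purely positional; birds that reappear far from
  where they vanished (carried, flapping) or amid close neighbors can be
  mis-associated, mirroring the reference procedure's own limits.
- The linear calibration assumes the pen fills the frame from directly
  above; off-nadir mounting or lens distortion needs an external
  homography first.
- Distance during occlusion gaps is not counted (by design), so heavily
  occluded birds under-report distance even after merging; appearance
  percentage flags when this matters.
- The simulator's waypoint walk has no social or diurnal structure; it
  validates the measurement chain, not behavioral realism.
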