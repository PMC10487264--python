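import itertools

import numpy as np
import pytest

from broilertrack.io_formats import BoundingBox, Detection, FrameDetections
from broilertrack.tracker import (
    KalmanState,
    TrackerParams,
    TrackerState,
    Tracklet,
    TrackStatus,
    associate,
    kf_init,
    kf_predict,
    kf_update,
    run_tracker,
    step,
)

PARAMS = TrackerParams()


def _det(frame, cx, cy, w=20.0, h=20.0, conf=1.0):
    return Detection(frame, BoundingBox(cx - w / 2, cy - h / 2, w, h), conf)


def _track_at(track_id, cx, cy):
    det = _det(0, cx, cy)
    t = Tracklet(track_id=track_id,
                 observations=[(0, det.box, det.box.centroid)],
                 state=kf_init(det, PARAMS), last_frame=0)
    return t


class TestKalman:
    def test_predict_advances_by_velocity(self):
        mean = np.array([0.0, 0.0, 10.0, 10.0, 2.0, 3.0, 0.0, 0.0])
        st = KalmanState(mean, np.eye(8))
        out = kf_predict(st, PARAMS)
        assert out.mean[:4] == pytest.approx([2.0, 3.0, 10.0, 10.0])
        # pure function: input untouched
        assert st.mean[0] == 0.0

    def test_zero_velocity_inflates_covariance(self):
        st = KalmanState(np.array([5.0, 5.0, 10.0, 10.0, 0, 0, 0, 0]), np.eye(8))
        out = kf_predict(st, PARAMS)
        assert out.mean[:2] == pytest.approx([5.0, 5.0])
        assert np.trace(out.covariance) > np.trace(st.covariance)

    def test_ten_predicts_closed_form(self):
        st = KalmanState(np.array([0.0, 0.0, 10, 10, 1.0, 1.0, 0, 0]), np.eye(8))
        for _ in range(10):
            st = kf_predict(st, PARAMS)
        assert st.mean[:2] == pytest.approx([10.0, 10.0])

    def test_update_zero_innovation_keeps_mean(self):
        det = _det(0, 50.0, 60.0)
        st = kf_update(kf_init(det, PARAMS), det, PARAMS)
        out = kf_update(st, det, PARAMS)
        assert out.mean[:4] == pytest.approx(st.mean[:4])

    def test_measurement_noise_zero_limit(self):
        params = TrackerParams(measurement_noise_scale=1e-6)
        st = kf_update(kf_init(_det(0, 100.0, 100.0), params),
                       _det(0, 100.0, 100.0), params)
        st = kf_predict(st, params)
        out = kf_update(st, _det(1, 137.0, 191.0), params)
        assert out.mean[0] == pytest.approx(137.0, abs=1e-6)
        assert out.mean[1] == pytest.approx(191.0, abs=1e-6)

    def test_update_rejects_non_finite(self):
        det = _det(0, 10, 10)
        st = kf_init(det, PARAMS)
        bad = Detection(0, BoundingBox(float("nan"), 0, 5, 5))
        with pytest.raises(FloatingPointError):
            kf_update(st, bad, PARAMS)

    def test_matches_independent_scalar_recursion(self):
        """The 8-state filter decouples into per-axis (position, velocity)
        filters; an independently coded 2-state KF must agree exactly."""
        rng = np.random.default_rng(4)
        zs = np.cumsum(rng.normal(2.0, 0.5, size=30)) + 100.0

        # independent scalar constant-velocity KF, same noise model
        F = np.array([[1.0, 1.0], [0.0, 1.0]])
        H = np.array([[1.0, 0.0]])
        q = PARAMS.process_noise_scale
        Q = np.diag([q**2, (q / 2.0) ** 2])
        R = np.array([[PARAMS.measurement_noise_scale**2]])
        m = np.array([zs[0], 0.0])
        P = np.diag([PARAMS.measurement_noise_scale**2, 1e4])
        # initial update mirrors kf_init followed by kf_update
        S = H @ P @ H.T + R
        K = P @ H.T / S
        m = m + (K * (zs[0] - m[0])).ravel()
        P = (np.eye(2) - K @ H) @ P @ (np.eye(2) - K @ H).T + K @ R @ K.T

        det0 = _det(0, zs[0], 50.0)
        st = kf_update(kf_init(det0, PARAMS), det0, PARAMS)
        for f, z in enumerate(zs[1:], start=1):
            m = F @ m
            P = F @ P @ F.T + Q
            S = H @ P @ H.T + R
            K = P @ H.T / S
            m = m + (K * (z - m[0])).ravel()
            I_KH = np.eye(2) - K @ H
            P = I_KH @ P @ I_KH.T + K @ R @ K.T

            st = kf_predict(st, PARAMS)
            st = kf_update(st, _det(f, z, 50.0), PARAMS)
        assert st.mean[0] == pytest.approx(m[0], rel=1e-10)
        assert st.mean[4] == pytest.approx(m[1], rel=1e-10)

    def test_constant_velocity_convergence(self):
        vx, vy = 1.5, -0.75
        det0 = _det(0, 200.0, 900.0)
        st = kf_update(kf_init(det0, PARAMS), det0, PARAMS)
        for f in range(1, 21):
            st = kf_predict(st, PARAMS)
            st = kf_update(st, _det(f, 200.0 + vx * f, 900.0 + vy * f), PARAMS)
        assert abs(st.mean[4] - vx) < 1e-6
        assert abs(st.mean[5] - vy) < 1e-6


class TestAssociate:
    def test_single_pair_within_gate(self):
        matches, ut, ud = associate(
            [_track_at(1, 100.0, 110.0)], [_det(1, 101.0, 110.0)],
            TrackerParams(gate_distance=10),
        )
        assert matches == [(0, 0)] and not ut and not ud

    def test_gating_dissolves_far_pair(self):
        matches, ut, ud = associate(
            [_track_at(1, 100.0, 110.0)], [_det(1, 150.0, 110.0)],
            TrackerParams(gate_distance=10),
        )
        assert not matches and ut == [0] and ud == [0]

    def test_empty_inputs(self):
        assert associate([], [], PARAMS) == ([], [], [])
        m, ut, ud = associate([], [_det(0, 100, 100)], PARAMS)
        assert not m and not ut and ud == [0]

    @pytest.mark.parametrize("n_tracks,n_dets", [(3, 3), (5, 5), (4, 6), (6, 4)])
    def test_optimal_against_bruteforce(self, n_tracks, n_dets):
        rng = np.random.default_rng(n_tracks * 10 + n_dets)
        for _ in range(25):
            tracks = [_track_at(i + 1, *rng.uniform(10, 1000, 2)) for i in range(n_tracks)]
            dets = [_det(1, *rng.uniform(10, 1000, 2)) for _ in range(n_dets)]
            params = TrackerParams(gate_distance=1e9)
            matches, _, _ = associate(tracks, dets, params)
            cost = np.array(
                [[np.hypot(t.state.mean[0] - d.box.centroid[0],
                           t.state.mean[1] - d.box.centroid[1])
                  for d in dets] for t in tracks]
            )
            got = sum(cost[i, j] for i, j in matches)
            k = min(n_tracks, n_dets)
            best = min(
                sum(cost[i, j] for i, j in zip(rows, perm))
                for rows in itertools.combinations(range(n_tracks), k)
                for perm in itertools.permutations(range(n_dets), k)
            )
            assert got == pytest.approx(best)


class TestStepLifecycle:
    def test_spawn_tentative_tracks(self):
        st = TrackerState(params=PARAMS)
        step(st, FrameDetections(0, [_det(0, 100, 100), _det(0, 500, 500),
                                     _det(0, 900, 900)]))
        assert [t.track_id for t in st.live] == [1, 2, 3]
        assert all(t.status is TrackStatus.TENTATIVE for t in st.live)

    def test_confirmation_after_min_hits(self):
        st = TrackerState(params=PARAMS)
        for f in range(PARAMS.min_hits):
            step(st, FrameDetections(f, [_det(f, 100 + f, 100)]))
        assert st.live[0].status is TrackStatus.CONFIRMED

    def test_confirmed_track_terminates_after_max_age(self):
        params = TrackerParams(max_age=3, min_hits=1)
        st = TrackerState(params=params)
        for f in range(3):
            step(st, FrameDetections(f, [_det(f, 100, 100)]), params)
        for f in range(3, 3 + params.max_age + 1):
            step(st, FrameDetections(f, []), params)
        assert not st.live
        assert len(st.finished) == 1
        assert st.finished[0].status is TrackStatus.LOST
        assert st.finished[0].observations[-1][0] == 2

    def test_out_of_order_frame_rejected(self):
        st = TrackerState(params=PARAMS)
        step(st, FrameDetections(5, []))
        with pytest.raises(ValueError, match="increasing"):
            step(st, FrameDetections(5, []))

    def test_ids_monotone_never_reused(self):
        params = TrackerParams(max_age=1, min_hits=1)
        st = TrackerState(params=params)
        ids = set()
        rng = np.random.default_rng(2)
        for f in range(40):
            dets = [_det(f, *rng.uniform(50, 2000, 2))
                    for _ in range(rng.integers(0, 4))]
            step(st, FrameDetections(f, dets), params)
            new = {t.track_id for t in st.live}
            assert max(new, default=0) <= st.next_id - 1
            ids |= new
        all_tracks = st.finished + st.live
        assert len({t.track_id for t in all_tracks}) == len(all_tracks)


class TestRunTracker:
    def test_empty_input(self):
        assert run_tracker([]) == []

    def test_noiseless_run_one_track_per_bird(self, noiseless_run):
        sim, _, frames, truth_map = noiseless_run
        tracklets = run_tracker(frames)
        assert len(tracklets) == sim.n_birds
        n_frames = len(frames)
        for t in tracklets:
            obs_frames = [f for f, _, _ in t.observations]
            assert obs_frames == list(range(n_frames))  # dense, time-sorted

    def test_forced_gap_splits_one_bird(self, fragment_run):
        sim, _, windows, frames, truth_map, params, tracklets = fragment_run
        assert len(tracklets) == sim.n_birds + 1
        (bird, (start, end)), = (
            (b, w[0]) for b, w in windows.items()
        )
        # the two fragments of the dropped bird are frame-disjoint
        pre = [t for t in tracklets if t.observations[-1][0] == start - 1]
        post = [t for t in tracklets if t.first_frame == end]
        assert len(pre) == 1 and len(post) == 1
        assert {f for f, _, _ in pre[0].observations}.isdisjoint(
            {f for f, _, _ in post[0].observations}
        )

    def test_one_observation_per_frame_per_track(self, fragment_run):
        *_, tracklets = fragment_run
        for t in tracklets:
            frames_seen = [f for f, _, _ in t.observations]
            assert len(frames_seen) == len(set(frames_seen))
            assert frames_seen == sorted(frames_seen)
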