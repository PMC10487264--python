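import pytest

from broilertrack.io_formats import RunConfig
from broilertrack.mobility import calibrate
from broilertrack.simulator import (
    NoiseConfig,
    SimConfig,
    inject_dropouts,
    render_detections,
    render_with_dropouts,
    simulate_motion,
)
from broilertrack.tracker import TrackerParams, run_tracker


@pytest.fixture(scope="session")
def calib():
    """Default pen/camera calibration: 100 x 150 cm onto 2592 x 1944 px."""
    return calibrate(100.0, 150.0, 2592.0, 1944.0)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(deadband=0.0)


@pytest.fixture(scope="session")
def noiseless_run(calib):
    """Small noiseless simulation: 12 birds, 120 s at 5 fps."""
    sim = SimConfig(n_birds=12, duration_s=120.0, frame_rate=5.0, seed=7)
    tracks = simulate_motion(sim)
    frames, truth_map = render_detections(
        tracks, NoiseConfig(), calib, seed=8,
        bird_radius_cm=sim.bird_radius_cm,
        image_width_px=2592.0, image_height_px=1944.0,
    )
    return sim, tracks, frames, truth_map


@pytest.fixture(scope="session")
def fragment_run(calib):
    """Noiseless 12-bird run with one injected dropout gap longer than the
    tracker's max_age, producing exactly 13 tracklets (one bird split)."""
    sim = SimConfig(n_birds=12, duration_s=120.0, frame_rate=5.0, seed=11)
    tracks = simulate_motion(sim)
    windows = inject_dropouts(
        tracks, n_gaps=1, min_gap_frames=8, max_gap_frames=12,
        distance_threshold_cm=30.0, seed=12,
    )
    assert sum(len(w) for w in windows.values()) == 1
    frames, truth_map = render_with_dropouts(
        tracks, windows, calib, seed=13,
        bird_radius_cm=sim.bird_radius_cm,
        image_width_px=2592.0, image_height_px=1944.0,
    )
    params = TrackerParams(max_age=5, min_hits=3)
    tracklets = run_tracker(frames, params)
    return sim, tracks, windows, frames, truth_map, params, tracklets
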