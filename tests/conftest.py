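import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sonolift import synthetic
from sonolift.mocap_io import MarkerRoleMap, MarkerTrajectory, TrajectorySet

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_session():
    """A clean 10-rep session with known faults and its exact ground truth."""
    cfg = synthetic.SimulationConfig(
        n_reps=10, rep_period=3.0, spine_fault_amplitude=0.4,
        barbell_drift=0.2, marker_noise_sd=0.0, seed=7)
    return synthetic.simulate_session(cfg)


@pytest.fixture(scope="session")
def roles():
    return synthetic.DEFAULT_ROLES


def constant_capture(markers: dict, n_frames: int = 120,
                     frame_rate: float = 100.0) -> TrajectorySet:
    """A static capture holding each marker at a fixed 3D point."""
    trajectories = {
        name: MarkerTrajectory(name, np.tile(np.asarray(p, float), (n_frames, 1)),
                               np.ones(n_frames, dtype=bool))
        for name, p in markers.items()
    }
    return TrajectorySet(frame_rate=frame_rate, trajectories=trajectories)


def eight_role_markers(spine_pts, bar_y=50.0, feet_y=0.0) -> dict:
    """Marker dict covering the eight required roles with configurable geometry."""
    l4, t12, t7, c2 = spine_pts
    return {
        "L4": l4, "T12": t12, "T7": t7, "C2": c2,
        "foot_front_L": (-100.0, feet_y, 0.0),
        "foot_front_R": (100.0, feet_y, 0.0),
        "barbell_end_L": (-800.0, bar_y, 200.0),
        "barbell_end_R": (800.0, bar_y, 200.0),
    }


IDENTITY_ROLES = MarkerRoleMap({
    "spine_L4": "L4", "spine_T12": "T12", "spine_T7": "T7", "spine_C2": "C2",
    "foot_front_left": "foot_front_L", "foot_front_right": "foot_front_R",
    "barbell_end_left": "barbell_end_L", "barbell_end_right": "barbell_end_R",
})
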