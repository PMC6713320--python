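"""Synthetic motion-capture sessions and cohorts with exact ground truth.

No public motion recordings exist for this task, so every other module is
exercised on generated captures that reproduce the capture conditions of the
original study: 22 labeled body markers plus 4 barbell markers sampled at
100 Hz, with controllable spine-flexion and barbell-drift fault amplitudes
and additive Gaussian marker noise.

Geometry (mm; x anteroposterior toward the athlete's front, z up).  The four
spine markers form a chain with fixed vertical spacings (150 / 200 / 150 mm);
T12 and T7 are displaced posteriorly by a common offset ``delta`` so the chain
length is ``2 * sqrt(150^2 + delta^2) + 200`` — analytically invertible, which
makes the per-frame ground-truth sb exact under the kinematics definitions.
The neutral pose carries a nonzero offset (40 mm) so the chain can both
lengthen (flexion, sb > 0) and shorten (extension, sb < 0, floor at
sb ~ -0.21).  The bar midpoint height follows one raised-cosine cycle per
repetition; its anteroposterior position drifts so that the per-frame
ground-truth bfd dips from 1 to the configured minimum at mid-lift.

The remaining 16 body markers (trousers, wrists, elbows, shoulders, head) are
kinematically plausible decoys rigidly attached to the moving body so parsers
and validators face realistic label sets; they carry no physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import EXPERTISE_LEVELS
from .errors import SonoliftError
from .kinematics import CalibrationProfile, derive_series
from .mocap_io import MarkerRoleMap, MarkerTrajectory, TrajectorySet
from .segmentation import retain_reps, segment_reps, summarize_session

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortConfig",
    "DEFAULT_ROLES",
    "REARWARD_AXIS",
    "simulate_session",
    "simulate_static_capture",
    "simulate_cohort",
    "session_summary_from_capture",
]

# fixed study-condition geometry (mm)
_SPINE_H1 = 150.0   # L4 -> T12 vertical spacing
_SPINE_H2 = 200.0   # T12 -> T7 (larger spacing: sport-top clearance)
_SPINE_H3 = 150.0   # T7 -> C2
_DELTA_NEUTRAL = 40.0
_DELTA_MAX = 100.0
_FOOT_X = 120.0     # toe markers forward of the bar's setup vertical plane
_FOOT_Y = 120.0
_BAR_HALF = 1000.0  # barbell extremity markers at y = +/- 1 m
_BAR_REST_Z = 225.0
_L4_BASE = np.array([-50.0, 0.0, 950.0])

#: The generator's athlete faces +x, so the rearward axis (toes -> body) is -x.
REARWARD_AXIS = np.array([-1.0, 0.0, 0.0])

DEFAULT_ROLES = MarkerRoleMap({
    "spine_L4": "L4", "spine_T12": "T12", "spine_T7": "T7", "spine_C2": "C2",
    "foot_front_left": "foot_front_L", "foot_front_right": "foot_front_R",
    "barbell_end_left": "barbell_end_L", "barbell_end_right": "barbell_end_R",
})

_DECOY_OFFSETS = {  # rigid offsets from the (moving) L4 base
    "trouser_1": (60.0, -110.0, -120.0), "trouser_2": (60.0, 110.0, -120.0),
    "trouser_3": (90.0, -90.0, -260.0), "trouser_4": (90.0, 90.0, -260.0),
    "trouser_5": (20.0, -130.0, -60.0), "trouser_6": (20.0, 130.0, -60.0),
    "shoulder_L": (30.0, -190.0, 520.0), "shoulder_R": (30.0, 190.0, 520.0),
    "head_1": (60.0, -70.0, 700.0), "head_2": (60.0, 70.0, 700.0),
    "head_3": (-40.0, -70.0, 720.0), "head_4": (-40.0, 70.0, 720.0),
}


def _chain_length(delta: float | np.ndarray):
    return 2.0 * np.sqrt(_SPINE_H1 ** 2 + np.square(delta)) + _SPINE_H2


def _delta_for_length(length: np.ndarray) -> np.ndarray:
    half = (np.asarray(length, dtype=float) - _SPINE_H2) / 2.0
    arg = np.square(half) - _SPINE_H1 ** 2
    if np.any(arg < -1e-9):
        raise SonoliftError(
            "requested spine chain shorter than the straight chain; "
            "keep sb above ~-0.21"
        )
    return np.sqrt(np.maximum(arg, 0.0))


_NEUTRAL_LEN = _chain_length(_DELTA_NEUTRAL)
_MAX_LEN = _chain_length(_DELTA_MAX)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one generated session.

    Defaults mirror the original capture protocol: 10 repetitions at an
    own-tempo middle-low pace (3 s per rep) recorded at 100 Hz with ~1 mm
    marker jitter.  ``spine_fault_amplitude`` is the peak per-frame true sb at
    mid-lift; ``barbell_drift`` the minimum per-frame true bfd.
    """

    n_reps: int = 10
    rep_period: float = 3.0          # s
    frame_rate: float = 100.0        # Hz
    spine_fault_amplitude: float = 0.4
    barbell_drift: float = 0.2
    marker_noise_sd: float = 1.0     # mm, i.i.d. Gaussian per coordinate
    seed: int = 0
    bar_travel_mm: float = 500.0
    spine_amp_jitter_sd: float = 0.0   # per-repetition sd of the fault amplitudes
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.rep_period > 0:
            raise ValueError("rep_period must be > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if self.marker_noise_sd < 0:
            raise ValueError("marker_noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generator-side values for a session."""

    sb: np.ndarray                  # per-frame true non-dimensional spine bend
    bfd: np.ndarray                 # per-frame true non-dimensional B-F distance
    rep_boundaries: np.ndarray      # frame indices, length n_reps + 1
    profile: CalibrationProfile
    rearward_axis: np.ndarray = field(default_factory=lambda: REARWARD_AXIS.copy())

    @property
    def n_reps(self) -> int:
        return len(self.rep_boundaries) - 1


def _body_frames(sb_true: np.ndarray, bfd_true: np.ndarray, lift_phase: np.ndarray,
                 cfg: SimulationConfig, rng) -> dict[str, np.ndarray]:
    n = len(sb_true)
    length = _NEUTRAL_LEN + sb_true * (_MAX_LEN - _NEUTRAL_LEN)
    delta = _delta_for_length(length)

    base = np.tile(_L4_BASE, (n, 1))
    base[:, 2] += 0.35 * cfg.bar_travel_mm * lift_phase  # torso rises with the lift

    markers: dict[str, np.ndarray] = {}
    markers["L4"] = base.copy()
    markers["T12"] = base + np.column_stack([-delta, np.zeros(n),
                                             np.full(n, _SPINE_H1)])
    markers["T7"] = base + np.column_stack([-delta, np.zeros(n),
                                            np.full(n, _SPINE_H1 + _SPINE_H2)])
    markers["C2"] = base + np.column_stack(
        [np.zeros(n), np.zeros(n), np.full(n, _SPINE_H1 + _SPINE_H2 + _SPINE_H3)])

    for name, off in _DECOY_OFFSETS.items():
        markers[name] = base + np.asarray(off)

    # feet planted on the floor
    markers["foot_front_L"] = np.tile([_FOOT_X, -_FOOT_Y, 25.0], (n, 1))
    markers["foot_front_R"] = np.tile([_FOOT_X, _FOOT_Y, 25.0], (n, 1))

    # barbell: vertical raised-cosine travel, anteroposterior drift sets bfd
    bar_x = _FOOT_X * (1.0 - bfd_true)
    bar_z = _BAR_REST_Z + cfg.bar_travel_mm * lift_phase
    markers["barbell_end_L"] = np.column_stack([bar_x, np.full(n, -_BAR_HALF), bar_z])
    markers["barbell_end_R"] = np.column_stack([bar_x, np.full(n, _BAR_HALF), bar_z])
    markers["barbell_clap_1"] = np.column_stack([bar_x, np.full(n, 800.0), bar_z])
    markers["barbell_clap_2"] = np.column_stack([bar_x, np.full(n, 850.0), bar_z])

    # hands on the bar: wrists track it, elbows hang between shoulders and wrists
    for side, sy in (("L", -1.0), ("R", 1.0)):
        wrist = np.column_stack([bar_x, np.full(n, sy * 260.0), bar_z + 40.0])
        markers[f"wrist_{side}"] = wrist
        markers[f"elbow_{side}"] = 0.5 * (wrist + markers[f"shoulder_{side}"])

    if cfg.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, cfg.marker_noise_sd, size=(n, 3))
    return markers


def _to_trajectory_set(markers: dict[str, np.ndarray], cfg: SimulationConfig) -> TrajectorySet:
    trajectories = {
        name: MarkerTrajectory(name, pos, np.ones(len(pos), dtype=bool))
        for name, pos in markers.items()
    }
    return TrajectorySet(frame_rate=cfg.frame_rate, trajectories=trajectories,
                         start_time=cfg.start_time)


def simulate_session(cfg: SimulationConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Generate one deadlift session capture with exact per-frame ground truth.

    Each repetition is one raised-cosine bar-height cycle; true sb rises from
    0 to the (per-rep) fault amplitude at mid-lift, true bfd dips from 1 to
    the (per-rep) drift minimum.  A fixed seed yields bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    frames_per_rep = int(round(cfg.rep_period * cfg.frame_rate))
    n = cfg.n_reps * frames_per_rep
    k = np.arange(n)
    tau = (k % frames_per_rep) / frames_per_rep
    phase = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
    rep_idx = k // frames_per_rep

    amps = np.full(cfg.n_reps, cfg.spine_fault_amplitude)
    drifts = np.full(cfg.n_reps, cfg.barbell_drift)
    if cfg.spine_amp_jitter_sd > 0:
        amps = amps + rng.normal(0.0, cfg.spine_amp_jitter_sd, cfg.n_reps)
        drifts = drifts + rng.normal(0.0, cfg.spine_amp_jitter_sd, cfg.n_reps)
    amps = np.maximum(amps, -0.2)  # analytic floor of the spine-chain geometry

    sb_true = amps[rep_idx] * phase
    bfd_true = 1.0 - (1.0 - drifts[rep_idx]) * phase

    markers = _body_frames(sb_true, bfd_true, phase, cfg, rng)
    capture = _to_trajectory_set(markers, cfg)
    truth = GroundTruth(
        sb=sb_true, bfd=bfd_true,
        rep_boundaries=np.arange(cfg.n_reps + 1) * frames_per_rep,
        profile=CalibrationProfile(neutral_spine=_NEUTRAL_LEN,
                                   max_spine_bend=_MAX_LEN,
                                   initial_bf_distance=_FOOT_X),
    )
    return capture, truth


_STATIC_POSES = ("neutral_spine", "max_spine_bend", "initial_bfd")


def simulate_static_capture(pose: str, duration: float = 2.0,
                            marker_noise_sd: float = 1.0, seed: int = 0,
                            frame_rate: float = 100.0) -> TrajectorySet:
    """A static calibration capture for one of the three reference poses."""
    if pose not in _STATIC_POSES:
        raise ValueError(f"pose must be one of {_STATIC_POSES}")
    cfg = SimulationConfig(n_reps=1, rep_period=duration, frame_rate=frame_rate,
                           marker_noise_sd=marker_noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    sb = {"neutral_spine": 0.0, "max_spine_bend": 1.0, "initial_bfd": 0.0}[pose]
    markers = _body_frames(np.full(n, sb), np.ones(n), np.zeros(n), cfg, rng)
    return _to_trajectory_set(markers, cfg)


def session_summary_from_capture(capture: TrajectorySet, truth: GroundTruth,
                                 participant_id: str, condition: str,
                                 roles: MarkerRoleMap = DEFAULT_ROLES):
    """Run the full derive -> segment -> retain -> summarize pipeline."""
    from .segmentation import bar_height

    derived = derive_series(capture, roles, truth.profile, truth.rearward_axis)
    reps = segment_reps(bar_height(capture, roles), capture.frame_rate)
    retained = retain_reps(reps)
    return summarize_session(derived, retained, participant_id, condition,
                             n_reps_detected=len(reps))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a simulated two-group cohort.

    Group sizes and effect magnitudes default to the original study's scale:
    16 instruction vs 15 sonification participants, a mean within-group sb
    improvement of -0.12 with between-subject sd 0.15, and a mean bfd
    improvement of +0.65.  Baselines are drawn per participant around the
    control-condition distributions (mean sb ~ 0.02, mean bfd ~ 0.4).
    """

    n_instruction: int = 16
    n_sonification: int = 15
    effect_sb: float = -0.12      # mean session-level sb improvement (feedback - control)
    effect_bfd: float = 0.65      # mean session-level bfd improvement
    between_sd_sb: float = 0.15   # between-subject sd of the sb effect
    between_sd_bfd: float = 0.70
    baseline_sb_mean: float = 0.35   # control-session peak fault scale (amplitude/2 ~ mean)
    baseline_sb_sd: float = 0.10
    baseline_bfd_mean: float = 0.40
    baseline_bfd_sd: float = 0.30
    within_sd: float = 0.05       # per-repetition jitter of fault amplitudes
    expertise_mix: tuple[float, float, float] = (0.16, 0.48, 0.36)
    expertise_effect_bfd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    marker_noise_sd: float = 1.0
    n_reps: int = 10
    rep_period: float = 3.0
    condition: str = "combination"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_instruction, self.n_sonification) < 3:
            raise ValueError("group sizes must be >= 3")
        if abs(sum(self.expertise_mix) - 1.0) > 1e-9:
            raise ValueError("expertise_mix must sum to 1")


def simulate_cohort(cohort_cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full two-group study and run every session through the pipeline.

    For each participant a control and a feedback session are generated with
    :func:`simulate_session` (participant-level random baselines and effects,
    repetition-level jitter, marker noise) and summarized by the segmentation
    module.  Returns ``(cohort, truth)``: the tidy cohort table the analysis
    module consumes, and a per-participant table of the generating
    (ground-truth) session means and effects.
    """
    cc = cohort_cfg
    rng = np.random.default_rng(cc.seed)
    levels = np.array(EXPERTISE_LEVELS)
    rows, truth_rows = [], []
    pid_counter = 0
    for group, n_group in (("instruction", cc.n_instruction),
                           ("sonification", cc.n_sonification)):
        for _ in range(n_group):
            pid = f"P{pid_counter:02d}"
            pid_counter += 1
            expertise = rng.choice(levels, p=cc.expertise_mix)
            sex = rng.choice(["F", "M"])
            exp_shift = cc.expertise_effect_bfd[list(levels).index(expertise)]

            # participant-level true session means (mean over the lift cycle
            # is amplitude/2 for the raised-cosine profile)
            ctrl_sb = rng.normal(cc.baseline_sb_mean, cc.baseline_sb_sd)
            ctrl_bfd = rng.normal(cc.baseline_bfd_mean, cc.baseline_bfd_sd)
            eff_sb = rng.normal(cc.effect_sb, cc.between_sd_sb)
            eff_bfd = rng.normal(cc.effect_bfd, cc.between_sd_bfd) + exp_shift
            fb_sb = ctrl_sb + eff_sb
            fb_bfd = ctrl_bfd + eff_bfd

            targets = {"control": (ctrl_sb, ctrl_bfd),
                       cc.condition: (fb_sb, fb_bfd)}
            ratings = {f"rating_{c}": int(rng.integers(1, 8))
                       for c in ("clarity", "pleasantness", "motivation")}
            for condition, (m_sb, m_bfd) in targets.items():
                amp = max(2.0 * m_sb, -0.18)          # session mean -> peak amplitude
                drift = 2.0 * m_bfd - 1.0             # mean bfd -> mid-lift minimum
                cfg = SimulationConfig(
                    n_reps=cc.n_reps, rep_period=cc.rep_period,
                    spine_fault_amplitude=amp, barbell_drift=drift,
                    marker_noise_sd=cc.marker_noise_sd,
                    spine_amp_jitter_sd=2.0 * cc.within_sd,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                capture, truth = simulate_session(cfg)
                summ = session_summary_from_capture(capture, truth, pid, condition)
                rows.append({
                    "participant_id": pid, "group": group,
                    "expertise": str(expertise), "sex": str(sex),
                    "condition": condition,
                    "mean_sb": summ.mean_sb, "mean_bfd": summ.mean_bfd,
                    "n_reps_detected": summ.n_reps_detected,
                    "n_reps_retained": summ.n_reps_retained,
                    **ratings,
                })
            truth_rows.append({
                "participant_id": pid, "group": group, "expertise": str(expertise),
                "true_control_sb": ctrl_sb, "true_control_bfd": ctrl_bfd,
                "true_effect_sb": eff_sb, "true_effect_bfd": eff_bfd,
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)

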