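"""Per-frame deadlift kinematics: spine-bend length, barbell-foot distance,
static-pose calibration and the non-dimensional quantities sb and bfd.

Two physical quantities drive the feedback:

* **spine bend** — the length of the vertebral marker chain
  ``|L4-T12| + |T12-T7| + |T7-C2|`` (mm).  Forward flexion under load
  lengthens the chain; this is the injury-relevant fault.
* **barbell-foot (B-F) distance** — the horizontal perpendicular distance from
  the front-foot (toe) markers to the line through the barbell extremities,
  taking the smaller of the two feet.  Signed: positive while the bar stays on
  the body side of the toe markers (correct, bar over mid-foot), negative once
  the bar drifts beyond the toes.

Per-athlete calibration (three static poses: neutral spine, maximal spine
bend, initial B-F distance) turns both into dimensionless series::

    sb  = (spine_bend - neutral_spine) / (max_spine_bend - neutral_spine)
    bfd = bf_distance / initial_bf_distance

so sb = 0 at the athlete's neutral back, sb = 1 at the instructed maximal
fault, bfd = 1 at the setup bar position and bfd = 0 at the toes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, GeometryError
from .mocap_io import MarkerRoleMap, TrajectorySet

__all__ = [
    "CalibrationProfile",
    "DerivedSeries",
    "spine_length",
    "bf_distance",
    "estimate_rearward_axis",
    "calibrate",
    "normalize",
    "derive_series",
]


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-athlete reference values from the three static calibration poses."""

    neutral_spine: float        # mm, chain length with unloaded neutral back
    max_spine_bend: float       # mm, chain length at instructed maximal fault
    initial_bf_distance: float  # mm, horizontal bar-foot distance at setup

    def __post_init__(self) -> None:
        if not self.max_spine_bend > self.neutral_spine:
            raise CalibrationError(
                f"max_spine_bend ({self.max_spine_bend}) must exceed "
                f"neutral_spine ({self.neutral_spine})"
            )
        if not self.initial_bf_distance > 0:
            raise CalibrationError(
                f"initial_bf_distance must be > 0, got {self.initial_bf_distance}"
            )


@dataclass
class DerivedSeries:
    """Per-frame derived kinematics; NaN where a required marker was occluded."""

    time: np.ndarray        # s
    spine_bend: np.ndarray  # mm
    bf_distance: np.ndarray  # mm, signed
    sb: np.ndarray          # dimensionless
    bfd: np.ndarray         # dimensionless

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("spine_bend", "bf_distance", "sb", "bfd"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"DerivedSeries field {name} length mismatch")


def spine_length(p_l4, p_t12, p_t7, p_c2) -> np.ndarray | float:
    """Chain length |L4-T12| + |T12-T7| + |T7-C2| in mm.

    Accepts single points (shape (3,)) or stacked frames (shape (n, 3)).
    Invariant under any rigid motion applied to all four points.  Frames with
    non-finite coordinates yield NaN rather than raising.
    """
    pts = [np.asarray(p, dtype=float) for p in (p_l4, p_t12, p_t7, p_c2)]
    d0 = np.linalg.norm(pts[1] - pts[0], axis=-1)
    d1 = np.linalg.norm(pts[2] - pts[1], axis=-1)
    d2 = np.linalg.norm(pts[3] - pts[2], axis=-1)
    return d0 + d1 + d2


def bf_distance(barbell_left, barbell_right, foot_left, foot_right,
                rearward_axis, mode: str = "perpendicular") -> np.ndarray | float:
    """Signed horizontal barbell-foot distance in mm; the smaller foot wins.

    All points are projected onto the floor plane (x, y).  For each front-foot
    marker the perpendicular distance to the infinite line through the barbell
    extremities is computed; the foot with the smaller magnitude is kept.  The
    sign is positive when the bar line is displaced from that foot along
    ``rearward_axis`` — a horizontal unit vector pointing from the toe markers
    toward the athlete's body — so a correctly positioned bar (over mid-foot,
    behind the toes) measures positive and a bar past the toes negative.

    ``mode='axis'`` instead projects the foot-to-line offset onto the rearward
    axis itself (distance measured along the anteroposterior axis rather than
    perpendicular to the bar); exposed for comparison, identical when the bar
    is perpendicular to the axis.
    """
    bl = np.asarray(barbell_left, dtype=float)[..., :2]
    br = np.asarray(barbell_right, dtype=float)[..., :2]
    feet = [np.asarray(foot_left, dtype=float)[..., :2],
            np.asarray(foot_right, dtype=float)[..., :2]]
    axis = np.asarray(rearward_axis, dtype=float)[:2]
    norm = np.linalg.norm(axis)
    if not norm > 0:
        raise GeometryError("rearward_axis must have a nonzero horizontal component")
    axis = axis / norm

    u = br - bl
    ulen = np.linalg.norm(u, axis=-1)
    scalar = bl.ndim == 1
    if scalar:
        if not ulen > 0:
            raise GeometryError("barbell endpoints coincide after horizontal projection")
    elif np.any(ulen[np.isfinite(ulen)] == 0):
        raise GeometryError("barbell endpoints coincide after horizontal projection")
    uhat = u / np.where(ulen == 0, np.nan, ulen)[..., None]
    # horizontal normal to the bar line, oriented toward rearward_axis
    n = np.stack([-uhat[..., 1], uhat[..., 0]], axis=-1)
    flip = np.sign(np.sum(n * axis, axis=-1))
    n = n * np.where(flip == 0, 1.0, flip)[..., None]

    if mode == "perpendicular":
        signed = [np.sum((bl - f) * n, axis=-1) for f in feet]
    elif mode == "axis":
        # offset from foot to its perpendicular projection on the line, along axis
        signed = []
        for f in feet:
            w = bl - f
            perp = w - np.sum(w * uhat, axis=-1)[..., None] * uhat
            signed.append(np.sum(perp * axis, axis=-1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    s0, s1 = signed
    pick = np.abs(s1) < np.abs(s0)
    out = np.where(pick, s1, s0)
    return float(out) if scalar else out


def estimate_rearward_axis(capture: TrajectorySet, roles: MarkerRoleMap) -> np.ndarray:
    """Horizontal unit vector from the mid-front-foot point toward L4.

    Estimated from the valid frames of a static capture; fixes the sign of
    :func:`bf_distance` so the setup bar position measures positive.
    """
    roles.validate_against(capture)
    l4 = capture.trajectories[roles["spine_L4"]]
    fl = capture.trajectories[roles["foot_front_left"]]
    fr = capture.trajectories[roles["foot_front_right"]]
    ok = l4.valid_mask & fl.valid_mask & fr.valid_mask
    if not np.any(ok):
        raise CalibrationError("no frame with L4 and both foot markers valid")
    midfoot = 0.5 * (fl.positions[ok] + fr.positions[ok])
    v = np.median(l4.positions[ok] - midfoot, axis=0)[:2]
    if not np.linalg.norm(v) > 0:
        raise GeometryError("L4 projects onto the mid-foot point; axis undefined")
    axis = np.zeros(3)
    axis[:2] = v / np.linalg.norm(v)
    return axis


_POSES = ("neutral_spine", "max_spine_bend", "initial_bfd")


def calibrate(static_capture: TrajectorySet, roles: MarkerRoleMap, pose: str,
              window: float = 1.0, rearward_axis=None) -> float:
    """Reference value (mm) from a short static pose capture.

    ``pose`` is one of ``neutral_spine`` / ``max_spine_bend`` (median spine
    chain length over the window) or ``initial_bfd`` (median signed barbell-
    foot distance).  The window is the central ``window`` seconds of the
    capture, which avoids settle-in and release transients; the median resists
    marker jitter.  Requires the needed markers valid in at least half of the
    window's frames.
    """
    if pose not in _POSES:
        raise ValueError(f"pose must be one of {_POSES}, got {pose!r}")
    roles.validate_against(static_capture)
    if static_capture.duration < window:
        raise CalibrationError(
            f"{pose}: capture of {static_capture.duration:.3f} s shorter than "
            f"window {window} s"
        )
    n = static_capture.n_frames
    w = max(1, int(round(window * static_capture.frame_rate)))
    lo = (n - w) // 2
    sl = slice(lo, lo + w)

    if pose in ("neutral_spine", "max_spine_bend"):
        pts = [static_capture.trajectories[roles[r]]
               for r in ("spine_L4", "spine_T12", "spine_T7", "spine_C2")]
        ok = np.logical_and.reduce([p.valid_mask[sl] for p in pts])
        values = spine_length(*(p.positions[sl] for p in pts))
    else:
        if rearward_axis is None:
            rearward_axis = estimate_rearward_axis(static_capture, roles)
        pts = [static_capture.trajectories[roles[r]]
               for r in ("barbell_end_left", "barbell_end_right",
                         "foot_front_left", "foot_front_right")]
        ok = np.logical_and.reduce([p.valid_mask[sl] for p in pts])
        values = bf_distance(*(p.positions[sl] for p in pts), rearward_axis)
    if np.count_nonzero(ok) < 0.5 * w:
        raise CalibrationError(
            f"{pose}: required markers valid in only {np.count_nonzero(ok)}/{w} "
            f"window frames"
        )
    return float(np.median(np.asarray(values)[ok]))


def normalize(spine_bend, bf_dist, profile: CalibrationProfile):
    """Non-dimensional (sb, bfd) from mm series and a calibration profile.

    ``sb = (spine_bend - neutral) / (max - neutral)``;
    ``bfd = bf_distance / initial_bf_distance``.  Affine, order-preserving;
    NaN propagates.
    """
    spine_bend = np.asarray(spine_bend, dtype=float)
    bf_dist = np.asarray(bf_dist, dtype=float)
    sb = (spine_bend - profile.neutral_spine) / (
        profile.max_spine_bend - profile.neutral_spine)
    bfd = bf_dist / profile.initial_bf_distance
    return sb, bfd


def derive_series(capture: TrajectorySet, roles: MarkerRoleMap,
                  profile: CalibrationProfile, rearward_axis,
                  bf_mode: str = "perpendicular") -> DerivedSeries:
    """Full per-frame derivation for a session capture.

    Frames where any required marker is occluded yield NaN in every derived
    column; downstream means skip them.
    """
    roles.validate_against(capture)
    spine = [capture.trajectories[roles[r]]
             for r in ("spine_L4", "spine_T12", "spine_T7", "spine_C2")]
    bar_feet = [capture.trajectories[roles[r]]
                for r in ("barbell_end_left", "barbell_end_right",
                          "foot_front_left", "foot_front_right")]
    spine_ok = np.logical_and.reduce([p.valid_mask for p in spine])
    bf_ok = np.logical_and.reduce([p.valid_mask for p in bar_feet])

    sp = np.asarray(spine_length(*(p.positions for p in spine)), dtype=float)
    sp[~spine_ok] = np.nan
    with np.errstate(invalid="ignore"):
        bf = np.asarray(
            bf_distance(*(p.positions for p in bar_feet), rearward_axis,
                        mode=bf_mode),
            dtype=float)
    bf[~bf_ok] = np.nan
    sb, bfd = normalize(sp, bf, profile)
    return DerivedSeries(time=capture.time, spine_bend=sp, bf_distance=bf,
                         sb=sb, bfd=bfd)
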