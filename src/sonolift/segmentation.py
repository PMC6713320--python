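"""Repetition segmentation from the vertical barbell trajectory, the
head/tail discard rule, and per-session summaries.

A set of deadlifts appears in the bar-midpoint height as a train of lift
cycles: floor, pull to lockout, return.  Repetitions are detected on the
4 Hz low-passed height signal as prominent peaks (lockouts) separated by at
least a minimum period; each repetition spans valley to valley around one
peak.  Transient effects at the start and end of a set are removed by
discarding the first three and last two repetitions, and one mean of each
measured quantity over the retained repetitions summarizes a session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import SegmentationError, SummaryError

__all__ = [
    "Repetition",
    "SessionSummary",
    "bar_height",
    "segment_reps",
    "retain_reps",
    "summarize_session",
]

CONDITIONS = ("control", "spine", "barbell", "combination")


@dataclass(frozen=True)
class Repetition:
    """One deadlift: half-open frame span [start_frame, end_frame) with the
    lift apex at top_frame, plus per-repetition mean kinematics."""

    index: int          # 1-based temporal order
    start_frame: int
    top_frame: int      # frame of maximal bar height within the span
    end_frame: int      # exclusive
    mean_sb: float = np.nan
    mean_bfd: float = np.nan

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise SegmentationError(
                f"rep {self.index}: start_frame must precede end_frame"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SessionSummary:
    """Repetition-averaged metrics for one participant x condition."""

    participant_id: str
    condition: str
    n_reps_detected: int
    n_reps_retained: int
    mean_sb: float
    mean_bfd: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


def bar_height(capture, roles) -> np.ndarray:
    """Vertical (z) midpoint of the two barbell-extremity markers, mm; NaN when occluded."""
    left = capture.trajectories[roles["barbell_end_left"]]
    right = capture.trajectories[roles["barbell_end_right"]]
    z = 0.5 * (left.positions[:, 2] + right.positions[:, 2])
    z = np.asarray(z, dtype=float)
    z[~(left.valid_mask & right.valid_mask)] = np.nan
    return z


def _lowpass(x: np.ndarray, frame_rate: float, cutoff: float = 4.0) -> np.ndarray:
    nyq = frame_rate / 2.0
    if cutoff >= nyq:
        return x
    b, a = sps.butter(2, cutoff / nyq)
    padlen = min(3 * max(len(a), len(b)), len(x) - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def segment_reps(bar_z: np.ndarray, frame_rate: float,
                 min_amplitude_frac: float = 0.5,
                 min_period: float = 1.0) -> list[Repetition]:
    """Split a vertical bar trajectory into repetitions.

    The height signal is low-passed at 4 Hz; lockout peaks are detected with
    prominence >= ``min_amplitude_frac`` x (signal range) and separation >=
    ``min_period`` seconds; each repetition spans valley to valley around one
    peak (interior boundaries are the minima between consecutive peaks, shared
    boundary frames belong to the later repetition).  A flat signal yields an
    empty list.
    """
    bar_z = np.asarray(bar_z, dtype=float)
    if not np.all(np.isfinite(bar_z)):
        raise SegmentationError("bar height contains non-finite values; gap-fill first")
    if len(bar_z) < 2 * frame_rate:
        raise SegmentationError(
            f"need at least 2 s of frames, got {len(bar_z) / frame_rate:.2f} s"
        )
    smooth = _lowpass(bar_z, frame_rate)
    rng = float(np.ptp(smooth))
    if rng <= 0:
        return []
    peaks, _ = sps.find_peaks(
        smooth,
        prominence=min_amplitude_frac * rng,
        distance=max(1, int(round(min_period * frame_rate))),
    )
    if len(peaks) == 0:
        return []
    # valley boundaries: capture edges outside, minima between peaks inside
    bounds = [int(np.argmin(smooth[: peaks[0] + 1]))]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(smooth[a:b + 1])))
    bounds.append(peaks[-1] + int(np.argmin(smooth[peaks[-1]:])) )
    reps = []
    for i, peak in enumerate(peaks):
        start = bounds[i]
        end = bounds[i + 1] if i + 1 < len(peaks) else bounds[i + 1] + 1
        reps.append(Repetition(index=i + 1, start_frame=start,
                               top_frame=int(peak), end_frame=int(end)))
    return reps


def attach_rep_means(reps: list[Repetition], derived) -> list[Repetition]:
    """Return repetitions with mean_sb / mean_bfd filled from a DerivedSeries
    (NaN frames excluded)."""
    out = []
    for r in reps:
        sl = slice(r.start_frame, r.end_frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN reps -> NaN
            mean_sb = float(np.nanmean(derived.sb[sl]))
            mean_bfd = float(np.nanmean(derived.bfd[sl]))
        out.append(Repetition(index=r.index, start_frame=r.start_frame,
                              top_frame=r.top_frame, end_frame=r.end_frame,
                              mean_sb=mean_sb, mean_bfd=mean_bfd))
    return out


def retain_reps(reps: list[Repetition], discard_head: int = 3,
                discard_tail: int = 2) -> list[Repetition]:
    """Drop the first ``discard_head`` and last ``discard_tail`` repetitions.

    Removes set-transient effects; with the defaults a 10-rep set keeps the
    middle five.  If nothing would remain, returns an empty list and warns.
    """
    stop = len(reps) - discard_tail
    if stop <= discard_head:
        warnings.warn(
            f"discard rule ({discard_head} head, {discard_tail} tail) leaves no "
            f"repetitions out of {len(reps)}"
        )
        return []
    return list(reps[discard_head:stop])


def summarize_session(derived, reps: list[Repetition], participant_id: str,
                      condition: str, n_reps_detected: int | None = None,
                      pooled: bool = False) -> SessionSummary:
    """Session summary over retained repetitions.

    Default is the two-stage mean (unweighted mean of per-repetition means,
    robust to repetition-duration variation); ``pooled=True`` averages all
    retained frames directly.  Repetitions whose frames are entirely missing
    for a quantity are excluded from that quantity's mean.
    """
    if not reps:
        raise SummaryError(
            f"session {participant_id}/{condition}: no retained repetitions"
        )
    reps = attach_rep_means(reps, derived)
    if pooled:
        frames = np.concatenate(
            [np.arange(r.start_frame, r.end_frame) for r in reps])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_sb = float(np.nanmean(derived.sb[frames]))
            mean_bfd = float(np.nanmean(derived.bfd[frames]))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_sb = float(np.nanmean([r.mean_sb for r in reps]))
            mean_bfd = float(np.nanmean([r.mean_bfd for r in reps]))
    return SessionSummary(
        participant_id=participant_id, condition=condition,
        n_reps_detected=len(reps) if n_reps_detected is None else n_reps_detected,
        n_reps_retained=len(reps), mean_sb=mean_sb, mean_bfd=mean_bfd,
    )
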