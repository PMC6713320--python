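"""Logistic mapping from movement quantities to audio-control parameters, and
an offline renderer that applies those controls to a music track.

The feedback mechanism maps each non-dimensional movement quantity x through
a decreasing logistic transfer function

    y = 1 - 1 / (1 + exp(-alpha * (x - beta)))

with steepness ``alpha`` and midpoint ``beta`` tuned per channel:

* spine channel (``alpha=10, beta=0.2``): y is the *quality* input of the
  degradation effect — 1 leaves the music pristine, values toward 0 produce a
  metallic aliasing distortion.  The ``beta`` margin means small spine
  deviations stay inaudible; flexion past the margin degrades the music.
* barbell channel (``alpha=15, beta=0.6``): y and 1-y are counterbalanced
  gains of a frontal speaker group and the full surround array.  As the bar
  drifts toward the toes (bfd -> 0) the sound collapses to the front; at or
  beyond the setup distance (bfd >= 1) the full immersive image plays.

Offline rendering realizes the degradation as sample-and-hold decimation with
hold length ``round(1 / max(quality, q_min))`` samples, piecewise-constant per
10 ms control frame, and the spatial cue as a crossfade between a mono
("front") downmix and the original full-width image.

Streaming contract (documented only; no transport is implemented here):
inbound messages carry ``(timestamp, marker positions)``, outbound messages
carry ``(timestamp, quality, gain_front, gain_surround)``; the latency budget
is one control frame (10 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.special import expit

from .errors import ContractError

__all__ = [
    "MappingParams",
    "SPINE_PARAMS",
    "BARBELL_PARAMS",
    "ControlSeries",
    "logistic_map",
    "spine_control",
    "barbell_control",
    "build_control_series",
    "render_feedback",
    "read_wav",
    "write_wav",
    "write_control_series",
    "read_control_series",
]


@dataclass(frozen=True)
class MappingParams:
    """Logistic transfer-function parameters: steepness alpha, midpoint beta."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


#: Defaults determined empirically for responsiveness with a distortion-free margin.
SPINE_PARAMS = MappingParams(alpha=10.0, beta=0.2)
BARBELL_PARAMS = MappingParams(alpha=15.0, beta=0.6)


def logistic_map(x, params: MappingParams = SPINE_PARAMS):
    """Decreasing logistic transfer: ``1 - 1/(1 + exp(-alpha*(x - beta)))``.

    Strictly decreasing in x, equals 0.5 at ``x = beta``, tends to 1 as
    x -> -inf and to 0 as x -> +inf.  Vectorized; NaN propagates.
    """
    x = np.asarray(x, dtype=float)
    out = expit(-params.alpha * (x - params.beta))
    return float(out) if out.ndim == 0 else out


def spine_control(sb, params: MappingParams = SPINE_PARAMS):
    """Audio quality in [0, 1] from non-dimensional spine bend.

    Quality 1 means pristine playback; forward flexion (sb above the beta
    margin) drives quality toward 0 and hence stronger degradation.  Spine
    extension (sb < 0) maps to quality ~1: only flexion is punished.
    """
    return logistic_map(sb, params)


def barbell_control(bfd, params: MappingParams = BARBELL_PARAMS):
    """(gain_front, gain_surround) from non-dimensional barbell-foot distance.

    ``gain_front = logistic_map(bfd)``, ``gain_surround = 1 - gain_front``;
    the two always sum to 1.  bfd -> 0 (bar at the toes) collapses the sound
    to the frontal speakers; bfd >= 1 restores the full surround image.
    """
    y = logistic_map(bfd, params)
    return y, 1.0 - y


@dataclass
class ControlSeries:
    """Per-control-frame audio parameters (10 ms frames at 100 Hz capture).

    ``gain_front + gain_surround == 1`` and all values lie in [0, 1] wherever
    the source frame was valid; frames whose kinematics were missing carry NaN
    throughout and are held over by the renderer.
    """

    time: np.ndarray
    quality: np.ndarray
    gain_front: np.ndarray
    gain_surround: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("quality", "gain_front", "gain_surround"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ContractError(f"ControlSeries field {name} length mismatch")
            ok = np.isfinite(arr)
            if np.any((arr[ok] < 0) | (arr[ok] > 1)):
                raise ContractError(f"ControlSeries field {name} outside [0, 1]")
        s = self.gain_front + self.gain_surround
        if not np.allclose(s[np.isfinite(s)], 1.0, atol=1e-9):
            raise ContractError("gain_front + gain_surround must equal 1 per frame")

    @property
    def frame_rate(self) -> float:
        if len(self.time) < 2:
            return 100.0
        return 1.0 / float(np.median(np.diff(self.time)))


def build_control_series(derived, spine_params: MappingParams = SPINE_PARAMS,
                         barbell_params: MappingParams = BARBELL_PARAMS) -> ControlSeries:
    """Map a :class:`~sonolift.kinematics.DerivedSeries` to audio controls."""
    quality = spine_control(derived.sb, spine_params)
    gf, gs = barbell_control(derived.bfd, barbell_params)
    return ControlSeries(time=np.asarray(derived.time, dtype=float),
                         quality=quality, gain_front=gf, gain_surround=gs)


# ---------------------------------------------------------------------------
# WAV I/O (PCM16 / PCM24-read / PCM32 / float32 via scipy)
# ---------------------------------------------------------------------------

def read_wav(path):
    """Read a WAV file -> (sample_rate, samples).  Mono (n,) or stereo (n, 2)."""
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ContractError(f"{path}: zero-length audio")
    return rate, data


def write_wav(path, sample_rate: int, samples: np.ndarray) -> None:
    wavfile.write(path, sample_rate, samples)


# ---------------------------------------------------------------------------
# offline rendering
# ---------------------------------------------------------------------------

def _ffill_control(arr: np.ndarray, neutral: float) -> np.ndarray:
    """Hold the last valid control value over missing frames (neutral at start)."""
    arr = np.asarray(arr, dtype=float).copy()
    good = np.isfinite(arr)
    if not good.any():
        arr[:] = neutral
        return arr
    idx = np.where(good, np.arange(len(arr)), 0)
    np.maximum.accumulate(idx, out=idx)
    arr = arr[idx]
    arr[~np.isfinite(arr)] = neutral  # leading gap before the first valid frame
    return arr


def _control_index(n_samples: int, sample_rate: float, control_rate: float,
                   n_control: int) -> np.ndarray:
    """Control-frame index per audio sample (zero-order hold, clipped to last)."""
    k = np.floor(np.arange(n_samples) * control_rate / sample_rate).astype(int)
    return np.clip(k, 0, n_control - 1)


def _sample_and_hold(x: np.ndarray, hold: np.ndarray) -> np.ndarray:
    """Per-sample hold lengths: out[k] = x[k - (k % hold[k])]."""
    k = np.arange(x.shape[0])
    src = k - (k % hold)
    return x[src]


def render_feedback(samples: np.ndarray, sample_rate: float, control: ControlSeries,
                    mode: str = "combination", q_min: float = 0.01) -> np.ndarray:
    """Apply movement-driven audio feedback to a track, offline.

    ``mode='spine'`` applies sample-and-hold degradation from ``quality``;
    ``mode='barbell'`` crossfades between a mono front downmix (gain_front)
    and the original full-width image (gain_surround); ``'combination'``
    composes degradation then gains.  Output has the input's length and dtype;
    identity controls (quality 1, gains (0, 1)) return bit-identical audio.
    """
    if mode not in ("spine", "barbell", "combination"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ContractError("zero-length audio")
    cr = control.frame_rate
    if cr > sample_rate:
        raise ContractError(
            f"control frame rate {cr:.1f} Hz exceeds audio sample rate {sample_rate}"
        )
    in_dtype = samples.dtype
    x = samples.astype(np.float64)
    mono = x.ndim == 1
    if mono:
        x = x[:, None]

    k = _control_index(x.shape[0], sample_rate, cr, len(control.time))
    if mode in ("spine", "combination"):
        q = _ffill_control(control.quality, neutral=1.0)
        hold = np.maximum(1, np.rint(1.0 / np.maximum(q, q_min)).astype(int))
        x = _sample_and_hold(x, hold[k])
    if mode in ("barbell", "combination"):
        gf = _ffill_control(control.gain_front, neutral=0.0)[k]
        gs = _ffill_control(control.gain_surround, neutral=1.0)[k]
        front = np.mean(x, axis=1, keepdims=True)  # mono downmix = frontal image
        x = gs[:, None] * x + gf[:, None] * front

    if mono:
        x = x[:, 0]
    if np.issubdtype(in_dtype, np.integer):
        info = np.iinfo(in_dtype)
        x = np.clip(np.rint(x), info.min, info.max).astype(in_dtype)
    else:
        x = x.astype(in_dtype)
    return x


# ---------------------------------------------------------------------------
# control-series CSV
# ---------------------------------------------------------------------------

def write_control_series(control: ControlSeries, path) -> None:
    """CSV columns: time, quality, gain_front, gain_surround."""
    cols = np.column_stack([control.time, control.quality,
                            control.gain_front, control.gain_surround])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("time,quality,gain_front,gain_surround\n")
        for row in cols:
            fh.write(",".join("" if not np.isfinite(v) else format(v, ".12g")
                              for v in row) + "\n")


def read_control_series(path) -> ControlSeries:
    data = np.genfromtxt(path, delimiter=",", skip_header=1, ndmin=2)
    if data.size == 0:
        raise ContractError(f"{path}: empty control series")
    return ControlSeries(time=data[:, 0], quality=data[:, 1],
                         gain_front=data[:, 2], gain_surround=data[:, 3])
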