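"""Reading, validating, gap-filling and writing marker-trajectory tables.

Optical motion-capture systems export labeled 3D marker positions per frame.
This module defines a small, documented plain-text schema in two dialects
(``tsv_wide`` and ``csv_long``), an in-memory container (:class:`TrajectorySet`),
linear gap filling for short occlusions, and the derived-record file the
feedback system stores alongside each session (one row per control frame:
marker positions, the non-dimensional quantities sb and bfd, and the audio
control values).

Coordinate convention: right-handed, z vertical (up), x anteroposterior
(positive toward the athlete's front), units millimetres, frame indexing
0-based with ``time = start_time + frame / frame_rate``.

tsv_wide dialect::

    #FRAME_RATE<TAB>100.0
    #START_TIME<TAB>0.0
    #ZERO_IS_MISSING<TAB>0            (optional; 1 treats (0,0,0) rows as occluded)
    frame<TAB>L4_x<TAB>L4_y<TAB>L4_z<TAB>T12_x ...
    0<TAB>12.1<TAB>...

Blank cells mark occluded coordinates; a frame of a marker is valid only when
all three coordinates are present.

csv_long dialect: columns ``frame,time,marker,x,y,z``; an absent
(frame, marker) row marks occlusion.  The frame rate is inferred from the
median time step.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ContractError, FormatError, StructureError

__all__ = [
    "MarkerTrajectory",
    "TrajectorySet",
    "MarkerRoleMap",
    "REQUIRED_ROLES",
    "read_trajectory_table",
    "write_trajectory_table",
    "fill_gaps",
    "write_derived_records",
    "read_derived_records",
    "DERIVED_RECORD_COLUMNS",
]

#: Roles every analysis needs mapped to concrete marker labels.
REQUIRED_ROLES = (
    "spine_L4",
    "spine_T12",
    "spine_T7",
    "spine_C2",
    "foot_front_left",
    "foot_front_right",
    "barbell_end_left",
    "barbell_end_right",
)


@dataclass
class MarkerTrajectory:
    """One labeled marker: positions in mm, shape (n_frames, 3), plus validity."""

    marker_id: str
    positions: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise StructureError(
                f"marker {self.marker_id!r}: positions must be (n, 3), "
                f"got {self.positions.shape}"
            )
        if self.valid_mask.shape != (self.positions.shape[0],):
            raise StructureError(
                f"marker {self.marker_id!r}: valid_mask length "
                f"{self.valid_mask.shape} does not match positions"
            )
        if not np.all(np.isfinite(self.positions[self.valid_mask])):
            raise StructureError(
                f"marker {self.marker_id!r}: non-finite coordinates flagged valid"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class TrajectorySet:
    """A capture: equal-length labeled marker trajectories at a fixed frame rate."""

    frame_rate: float
    trajectories: dict[str, MarkerTrajectory]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise StructureError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not self.trajectories:
            raise StructureError("a TrajectorySet needs at least one trajectory")
        lengths = {t.n_frames for t in self.trajectories.values()}
        if len(lengths) != 1:
            raise StructureError(f"ragged frame counts across markers: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.trajectories.values())).n_frames

    @property
    def marker_ids(self) -> list[str]:
        return list(self.trajectories)

    @property
    def time(self) -> np.ndarray:
        """Per-frame timestamps in seconds."""
        return self.start_time + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def positions(self, marker_id: str) -> np.ndarray:
        return self.trajectories[marker_id].positions

    def valid(self, marker_id: str) -> np.ndarray:
        return self.trajectories[marker_id].valid_mask

    def equals(self, other: "TrajectorySet", atol: float = 1e-9) -> bool:
        """Value equality: same markers, masks identical, valid coordinates within atol."""
        if set(self.trajectories) != set(other.trajectories):
            return False
        if self.n_frames != other.n_frames:
            return False
        if not np.isclose(self.frame_rate, other.frame_rate, atol=atol):
            return False
        if not np.isclose(self.start_time, other.start_time, atol=atol):
            return False
        for mid, tr in self.trajectories.items():
            ot = other.trajectories[mid]
            if not np.array_equal(tr.valid_mask, ot.valid_mask):
                return False
            m = tr.valid_mask
            if not np.allclose(tr.positions[m], ot.positions[m], atol=atol, rtol=0):
                return False
        return True


@dataclass(frozen=True)
class MarkerRoleMap:
    """Mapping from the eight functional roles to concrete marker labels."""

    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in REQUIRED_ROLES if r not in self.roles]
        if missing:
            raise StructureError(f"role map missing roles: {missing}")
        ids = [self.roles[r] for r in REQUIRED_ROLES]
        if len(set(ids)) != len(ids):
            raise StructureError("role map assigns one marker to multiple roles")

    def __getitem__(self, role: str) -> str:
        return self.roles[role]

    def validate_against(self, t: TrajectorySet) -> None:
        absent = [m for m in (self.roles[r] for r in REQUIRED_ROLES)
                  if m not in t.trajectories]
        if absent:
            raise StructureError(f"role-mapped markers absent from capture: {absent}")


# ---------------------------------------------------------------------------
# trajectory table I/O
# ---------------------------------------------------------------------------

def _open_text(path) -> io.TextIOBase:
    return open(path, "r", encoding="utf-8", newline="")


def read_trajectory_table(path, dialect: str = "tsv_wide") -> TrajectorySet:
    """Parse a marker-trajectory table in either supported dialect.

    Occluded coordinates (blank cells in tsv_wide; absent rows in csv_long;
    optionally exact (0,0,0) rows when the tsv_wide header sets
    ``ZERO_IS_MISSING`` to 1) yield ``valid_mask == False`` at those frames.
    """
    if dialect == "tsv_wide":
        return _read_tsv_wide(path)
    if dialect == "csv_long":
        return _read_csv_long(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv_wide' or 'csv_long'")


def _read_tsv_wide(path) -> TrajectorySet:
    frame_rate = None
    start_time = 0.0
    zero_is_missing = False
    header: list[str] | None = None
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                key = key.strip().upper()
                if key == "FRAME_RATE":
                    frame_rate = float(value)
                elif key == "START_TIME":
                    start_time = float(value)
                elif key == "ZERO_IS_MISSING":
                    zero_is_missing = value.strip() in ("1", "true", "True")
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                rows.append(cells)
    if frame_rate is None:
        raise FormatError(f"{path}: tsv_wide header must declare #FRAME_RATE")
    if header is None or header[0] != "frame":
        raise FormatError(f"{path}: missing column header starting with 'frame'")
    coord_cols = header[1:]
    if len(coord_cols) % 3 != 0:
        raise FormatError(f"{path}: coordinate columns not in x/y/z triplets")
    markers: list[str] = []
    for i in range(0, len(coord_cols), 3):
        triplet = coord_cols[i:i + 3]
        names = [c.rsplit("_", 1) for c in triplet]
        base = names[0][0]
        if [n[1] for n in names] != ["x", "y", "z"] or any(n[0] != base for n in names):
            raise FormatError(f"{path}: malformed coordinate triplet {triplet}")
        markers.append(base)
    if len(set(markers)) != len(markers):
        raise StructureError(f"{path}: duplicate marker labels in header")

    n = len(rows)
    pos = np.full((len(markers), n, 3), np.nan)
    for fi, cells in enumerate(rows):
        if len(cells) != 1 + 3 * len(markers):
            raise StructureError(
                f"{path}: row {fi} has {len(cells)} cells, expected {1 + 3 * len(markers)}"
            )
        for mi in range(len(markers)):
            for ci in range(3):
                cell = cells[1 + 3 * mi + ci].strip()
                if cell:
                    pos[mi, fi, ci] = float(cell)
    valid = np.all(np.isfinite(pos), axis=2)
    if zero_is_missing:
        valid &= ~np.all(pos == 0.0, axis=2)
    trajectories = {
        m: MarkerTrajectory(m, pos[i], valid[i]) for i, m in enumerate(markers)
    }
    return TrajectorySet(frame_rate=frame_rate, trajectories=trajectories,
                         start_time=start_time)


def _read_csv_long(path) -> TrajectorySet:
    frames: dict[tuple[int, str], np.ndarray] = {}
    times: dict[int, float] = {}
    markers: list[str] = []
    with _open_text(path) as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty csv_long file") from None
        expected = ["frame", "time", "marker", "x", "y", "z"]
        if [h.strip() for h in header] != expected:
            raise FormatError(f"{path}: csv_long header must be {expected}, got {header}")
        for row in reader:
            if not row:
                continue
            frame = int(row[0])
            times[frame] = float(row[1])
            marker = row[2]
            if marker not in markers:
                markers.append(marker)
            xyz = [float(c) if c.strip() else np.nan for c in row[3:6]]
            frames[(frame, marker)] = np.array(xyz)
    if not frames:
        raise FormatError(f"{path}: csv_long file has no data rows")
    frame_ids = sorted(times)
    if frame_ids != list(range(frame_ids[0], frame_ids[-1] + 1)):
        raise StructureError(f"{path}: frame indices are not contiguous")
    n = len(frame_ids)
    t_sorted = np.array([times[f] for f in frame_ids])
    if n >= 2:
        frame_rate = 1.0 / float(np.median(np.diff(t_sorted)))
    else:
        warnings.warn("single-frame csv_long capture: assuming 100 Hz")
        frame_rate = 100.0
    start_time = float(t_sorted[0]) - frame_ids[0] / frame_rate

    trajectories = {}
    for m in markers:
        pos = np.full((n, 3), np.nan)
        for i, f in enumerate(frame_ids):
            row = frames.get((f, m))
            if row is not None:
                pos[i] = row
        valid = np.all(np.isfinite(pos), axis=1)
        trajectories[m] = MarkerTrajectory(m, pos, valid)
    return TrajectorySet(frame_rate=frame_rate, trajectories=trajectories,
                         start_time=start_time)


def _fmt(v: float) -> str:
    # repr is the shortest exact round-trip decimal form of a double
    return "" if not np.isfinite(v) else repr(float(v))


def write_trajectory_table(t: TrajectorySet, path, dialect: str = "tsv_wide",
                           zero_is_missing: bool = False) -> None:
    """Write a TrajectorySet in either dialect; inverse of :func:`read_trajectory_table`."""
    path = Path(path)
    markers = t.marker_ids
    if dialect == "tsv_wide":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"#FRAME_RATE\t{format(t.frame_rate, '.12g')}\n")
            fh.write(f"#START_TIME\t{format(t.start_time, '.12g')}\n")
            if zero_is_missing:
                fh.write("#ZERO_IS_MISSING\t1\n")
            cols = ["frame"] + [f"{m}_{ax}" for m in markers for ax in "xyz"]
            fh.write("\t".join(cols) + "\n")
            for fi in range(t.n_frames):
                cells = [str(fi)]
                for m in markers:
                    tr = t.trajectories[m]
                    if tr.valid_mask[fi]:
                        cells.extend(_fmt(c) for c in tr.positions[fi])
                    else:
                        cells.extend(["", "", ""])
                fh.write("\t".join(cells) + "\n")
    elif dialect == "csv_long":
        time = t.time
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "time", "marker", "x", "y", "z"])
            for fi in range(t.n_frames):
                for m in markers:
                    tr = t.trajectories[m]
                    if tr.valid_mask[fi]:
                        writer.writerow([fi, _fmt(time[fi]), m,
                                         *(_fmt(c) for c in tr.positions[fi])])
            # keep frame indexing contiguous even if the last frames are all-occluded
            if t.n_frames and not any(
                t.trajectories[m].valid_mask[t.n_frames - 1] for m in markers
            ):
                raise ContractError(
                    "csv_long cannot represent a trailing fully-occluded frame"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def fill_gaps(t: TrajectorySet, max_gap_frames: int) -> TrajectorySet:
    """Linearly interpolate interior occlusion gaps of length <= max_gap_frames.

    Edge gaps (runs of invalid frames touching either end) and longer gaps are
    left untouched. Pure transform; idempotent.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    new = {}
    for mid, tr in t.trajectories.items():
        pos = tr.positions.copy()
        valid = tr.valid_mask.copy()
        n = tr.n_frames
        i = 0
        while i < n:
            if valid[i]:
                i += 1
                continue
            j = i
            while j < n and not valid[j]:
                j += 1
            gap_len = j - i
            interior = i > 0 and j < n
            if interior and gap_len <= max_gap_frames:
                p0, p1 = pos[i - 1], pos[j]
                for k in range(gap_len):
                    w = (k + 1) / (gap_len + 1)
                    pos[i + k] = (1 - w) * p0 + w * p1
                valid[i:j] = True
            i = j
        new[mid] = MarkerTrajectory(mid, pos, valid)
    return TrajectorySet(frame_rate=t.frame_rate, trajectories=new,
                         start_time=t.start_time)


# ---------------------------------------------------------------------------
# derived-record files
# ---------------------------------------------------------------------------

#: Fixed column order of the stored per-frame record (after the marker block):
#: timestamp, every marker's x/y/z, then sb, bfd, distortion level and the two
#: output channel volumes (right = surround array, left = frontal speakers).
DERIVED_RECORD_COLUMNS = ("time", "...markers...", "sb", "bfd",
                          "distortion", "volume_right", "volume_left")


def write_derived_records(t: TrajectorySet, d, c, path) -> None:
    """Store the session record: one row per control frame (10 ms at 100 Hz).

    ``d`` is a :class:`~sonolift.kinematics.DerivedSeries`; ``c`` is a
    :class:`~sonolift.sonification.ControlSeries` or ``None`` for control
    (no-sonification) sessions, in which case the distortion and volume
    columns are emitted as empty sentinels.
    """
    n = t.n_frames
    if len(d.sb) != n:
        raise ContractError(f"derived series length {len(d.sb)} != capture frames {n}")
    if c is not None and len(c.quality) != n:
        raise ContractError(f"control series length {len(c.quality)} != capture frames {n}")
    markers = t.marker_ids
    time = t.time
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#FRAME_RATE\t{format(t.frame_rate, '.12g')}\n")
        cols = (["time"] + [f"{m}_{ax}" for m in markers for ax in "xyz"]
                + ["sb", "bfd", "distortion", "volume_right", "volume_left"])
        fh.write("\t".join(cols) + "\n")
        for fi in range(n):
            cells = [_fmt(time[fi])]
            for m in markers:
                tr = t.trajectories[m]
                if tr.valid_mask[fi]:
                    cells.extend(_fmt(x) for x in tr.positions[fi])
                else:
                    cells.extend(["", "", ""])
            cells.append(_fmt(d.sb[fi]))
            cells.append(_fmt(d.bfd[fi]))
            if c is None:
                cells.extend(["", "", ""])
            else:
                cells.append(_fmt(c.quality[fi]))
                cells.append(_fmt(c.gain_surround[fi]))  # right channel: surround array
                cells.append(_fmt(c.gain_front[fi]))     # left channel: frontal speakers
            fh.write("\t".join(cells) + "\n")


def read_derived_records(path):
    """Read a derived-record file back: (TrajectorySet, sb, bfd, control or None).

    ``control`` is ``(quality, gain_front, gain_surround)`` arrays, or ``None``
    for control-session files whose sonification columns are empty.
    """
    frame_rate = None
    header = None
    rows = []
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                if key.strip().upper() == "FRAME_RATE":
                    frame_rate = float(value)
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
            else:
                rows.append(cells)
    if frame_rate is None or header is None:
        raise FormatError(f"{path}: missing #FRAME_RATE header or column header")
    if header[0] != "time" or header[-5:] != ["sb", "bfd", "distortion",
                                              "volume_right", "volume_left"]:
        raise FormatError(f"{path}: unexpected derived-record column layout")
    coord_cols = header[1:-5]
    markers = [coord_cols[i].rsplit("_", 1)[0] for i in range(0, len(coord_cols), 3)]
    n = len(rows)

    def cell(r, j):
        v = rows[r][j].strip()
        return float(v) if v else np.nan

    time = np.array([cell(r, 0) for r in range(n)])
    start_time = float(time[0]) if n else 0.0
    pos = np.full((len(markers), n, 3), np.nan)
    for r in range(n):
        for mi in range(len(markers)):
            for ci in range(3):
                pos[mi, r, ci] = cell(r, 1 + 3 * mi + ci)
    trajectories = {
        m: MarkerTrajectory(m, pos[i], np.all(np.isfinite(pos[i]), axis=1))
        for i, m in enumerate(markers)
    }
    base = 1 + 3 * len(markers)
    sb = np.array([cell(r, base) for r in range(n)])
    bfd = np.array([cell(r, base + 1) for r in range(n)])
    distortion = np.array([cell(r, base + 2) for r in range(n)])
    vol_right = np.array([cell(r, base + 3) for r in range(n)])
    vol_left = np.array([cell(r, base + 4) for r in range(n)])
    if n and np.all(np.isnan(distortion)) and np.all(np.isnan(vol_right)):
        control = None
    else:
        control = (distortion, vol_left, vol_right)  # quality, gain_front, gain_surround
    ts = TrajectorySet(frame_rate=frame_rate, trajectories=trajectories,
                       start_time=start_time) if markers else None
    return ts, sb, bfd, control
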