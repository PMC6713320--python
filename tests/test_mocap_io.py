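import numpy as np
import pytest
from hypothesis import given, strategies as st

from sonolift import synthetic
from sonolift.errors import FormatError, StructureError
from sonolift.kinematics import DerivedSeries
from sonolift.mocap_io import (MarkerRoleMap, MarkerTrajectory, TrajectorySet,
                               fill_gaps, read_derived_records,
                               read_trajectory_table, write_derived_records,
                               write_trajectory_table)
from sonolift.sonification import ControlSeries

TSV_FIXTURE = """#FRAME_RATE\t100.0
#START_TIME\t0.0
frame\tA_x\tA_y\tA_z\tB_x\tB_y\tB_z
0\t1\t2\t3\t10\t20\t30
1\t1.5\t2.5\t3.5\t11\t21\t31
2\t2\t3\t4\t12\t22\t32
"""

CSV_FIXTURE = """frame,time,marker,x,y,z
0,0.0,A,1,2,3
0,0.0,B,10,20,30
1,0.01,A,1.5,2.5,3.5
1,0.01,B,11,21,31
2,0.02,A,2,3,4
2,0.02,B,12,22,32
"""


def test_tsv_wide_parses_markers_and_frames(tmp_path):
    p = tmp_path / "cap.tsv"
    p.write_text(TSV_FIXTURE)
    t = read_trajectory_table(p, "tsv_wide")
    assert set(t.marker_ids) == {"A", "B"}
    assert t.n_frames == 3
    assert t.frame_rate == 100.0
    assert np.allclose(t.positions("A")[1], [1.5, 2.5, 3.5])
    assert t.valid("B").all()


def test_dialects_parse_to_equal_trajectory_sets(tmp_path):
    p1 = tmp_path / "cap.tsv"
    p1.write_text(TSV_FIXTURE)
    p2 = tmp_path / "cap.csv"
    p2.write_text(CSV_FIXTURE)
    t1 = read_trajectory_table(p1, "tsv_wide")
    t2 = read_trajectory_table(p2, "csv_long")
    assert t1.equals(t2)


def test_blank_cell_masks_single_frame(tmp_path):
    broken = TSV_FIXTURE.replace("1\t1.5\t2.5\t3.5", "1\t1.5\t\t3.5")
    p = tmp_path / "cap.tsv"
    p.write_text(broken)
    t = read_trajectory_table(p, "tsv_wide")
    assert list(t.valid("A")) == [True, False, True]
    assert t.valid("B").all()


def test_missing_frame_rate_header_is_format_error(tmp_path):
    p = tmp_path / "cap.tsv"
    p.write_text("\n".join(TSV_FIXTURE.splitlines()[1:]) + "\n")
    with pytest.raises(FormatError):
        read_trajectory_table(p, "tsv_wide")


def test_ragged_rows_are_structure_error(tmp_path):
    p = tmp_path / "cap.tsv"
    p.write_text(TSV_FIXTURE + "3\t1\t2\t3\n")
    with pytest.raises(StructureError):
        read_trajectory_table(p, "tsv_wide")


def test_zero_sentinel_only_with_header_flag(tmp_path):
    body = TSV_FIXTURE.replace("1\t1.5\t2.5\t3.5", "1\t0\t0\t0")
    p = tmp_path / "cap.tsv"
    p.write_text(body)
    assert read_trajectory_table(p, "tsv_wide").valid("A").all()
    p.write_text("#ZERO_IS_MISSING\t1\n" + body)
    assert list(read_trajectory_table(p, "tsv_wide").valid("A")) == [True, False, True]


@pytest.mark.parametrize("dialect", ["tsv_wide", "csv_long"])
def test_round_trip_on_synthetic_session(tmp_path, dialect):
    cfg = synthetic.SimulationConfig(n_reps=2, rep_period=2.0,
                                     marker_noise_sd=1.0, seed=11)
    capture, _ = synthetic.simulate_session(cfg)
    p = tmp_path / f"session.{dialect}"
    write_trajectory_table(capture, p, dialect)
    assert read_trajectory_table(p, dialect).equals(capture)


# --- gap filling ------------------------------------------------------------

def _one_marker(positions, valid):
    tr = MarkerTrajectory("M", np.asarray(positions, float),
                          np.asarray(valid, bool))
    return TrajectorySet(frame_rate=100.0, trajectories={"M": tr})


def test_fill_gaps_interpolates_single_frame_gap():
    t = _one_marker([[0, 0, 0], [np.nan] * 3, [2, 2, 2]], [True, False, True])
    out = fill_gaps(t, 1)
    assert out.valid("M").all()
    assert np.allclose(out.positions("M")[1], [1, 1, 1])


def test_fill_gaps_leaves_long_and_edge_gaps():
    nanrow = [np.nan] * 3
    t = _one_marker([[0, 0, 0], nanrow, nanrow, nanrow, [4, 4, 4]],
                    [True, False, False, False, True])
    out = fill_gaps(t, 2)
    assert list(out.valid("M")) == [True, False, False, False, True]
    t_edge = _one_marker([nanrow, [1, 1, 1], [2, 2, 2]], [False, True, True])
    out_edge = fill_gaps(t_edge, 5)
    assert list(out_edge.valid("M")) == [False, True, True]


@given(st.lists(st.booleans(), min_size=2, max_size=40),
       st.integers(min_value=0, max_value=5))
def test_fill_gaps_is_idempotent(mask, max_gap):
    n = len(mask)
    pos = np.arange(n * 3, dtype=float).reshape(n, 3)
    pos[~np.asarray(mask, bool)] = np.nan
    t = _one_marker(pos, mask)
    once = fill_gaps(t, max_gap)
    twice = fill_gaps(once, max_gap)
    assert once.equals(twice)


# --- derived-record files ---------------------------------------------------

def _small_session():
    cfg = synthetic.SimulationConfig(n_reps=1, rep_period=0.1,
                                     marker_noise_sd=0.0, seed=3)
    capture, truth = synthetic.simulate_session(cfg)
    d = DerivedSeries(time=capture.time, spine_bend=510 + truth.sb,
                      bf_distance=120 * truth.bfd, sb=truth.sb, bfd=truth.bfd)
    return capture, d


def test_derived_records_round_trip(tmp_path):
    capture, d = _small_session()
    n = capture.n_frames
    c = ControlSeries(time=capture.time, quality=np.linspace(1, 0.4, n),
                      gain_front=np.linspace(0, 1, n),
                      gain_surround=1 - np.linspace(0, 1, n))
    p = tmp_path / "rec.tsv"
    write_derived_records(capture, d, c, p)
    ts, sb, bfd, control = read_derived_records(p)
    assert ts.equals(capture)
    assert np.allclose(sb, d.sb, atol=1e-9)
    assert np.allclose(bfd, d.bfd, atol=1e-9)
    quality, gain_front, gain_surround = control
    assert np.allclose(quality, c.quality, atol=1e-9)
    assert np.allclose(gain_front, c.gain_front, atol=1e-9)
    assert np.allclose(gain_surround, c.gain_surround, atol=1e-9)


def test_control_session_emits_empty_sonification_columns(tmp_path):
    capture, d = _small_session()
    p = tmp_path / "rec.tsv"
    write_derived_records(capture, d, None, p)
    first_row = p.read_text().splitlines()[2]
    assert first_row.endswith("\t\t\t")  # distortion and volume sentinels empty
    *_, control = read_derived_records(p)
    assert control is None


def test_zero_frame_session_writes_header_only(tmp_path):
    tr = MarkerTrajectory("M", np.empty((0, 3)), np.empty(0, dtype=bool))
    t = TrajectorySet(frame_rate=100.0, trajectories={"M": tr})
    d = DerivedSeries(time=np.empty(0), spine_bend=np.empty(0),
                      bf_distance=np.empty(0), sb=np.empty(0), bfd=np.empty(0))
    p = tmp_path / "rec.tsv"
    write_derived_records(t, d, None, p)
    lines = p.read_text().splitlines()
    assert len(lines) == 2  # frame-rate header + column header, no data rows


def test_role_map_requires_all_roles_distinct():
    with pytest.raises(StructureError):
        MarkerRoleMap({"spine_L4": "L4"})
    good = {"spine_L4": "L4", "spine_T12": "T12", "spine_T7": "T7",
            "spine_C2": "C2", "foot_front_left": "FL", "foot_front_right": "FR",
            "barbell_end_left": "BL", "barbell_end_right": "BR"}
    MarkerRoleMap(good)
    bad = dict(good, spine_C2="L4")
    with pytest.raises(StructureError):
        MarkerRoleMap(bad)
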