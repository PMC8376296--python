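"""Head pose, per-frame kinematics, and trial feature vectors."""

import numpy as np
import pandas as pd
import pytest

from vpvigor import (
    EventLog,
    PoseSeries,
    TrackingSeries,
    head_pose,
    kinematic_series,
    movement_features,
    state_features,
)
from vpvigor.kinematics import MOVEMENT_VARIABLES, wrap_angle

from conftest import make_pose


def _tracking(red, green, fr=30.0):
    red = np.asarray(red, float)
    return TrackingSeries(np.arange(len(red)), red, np.asarray(green, float), fr)


# ---------------------------------------------------------------------------
# head pose

def test_pose_midpoint_and_axis_aligned_heading():
    tr = _tracking([[10, 0]] * 5, [[0, 0]] * 5)
    pose = head_pose(tr, front_led="red")
    assert np.allclose(pose.position, [5, 0])
    assert np.allclose(pose.heading, 0.0)

    tr = _tracking([[0, 10]] * 5, [[0, 0]] * 5)
    pose = head_pose(tr, front_led="red")
    assert np.allclose(pose.heading, np.pi / 2)


def test_pose_gap_interpolation_linear():
    red = np.array([[0.0, 0.0]] * 8)
    red[:, 0] = np.arange(8) * 3.0
    green = red - [2.0, 0.0]
    red_missing = red.copy()
    red_missing[3:6] = np.nan  # 3-frame dropout, within max_gap
    pose = head_pose(_tracking(red_missing, green))
    expect = head_pose(_tracking(red, green))
    assert pose.valid.all()
    assert np.allclose(pose.position, expect.position, atol=1e-12)


def test_pose_long_gap_stays_invalid():
    red = np.tile([10.0, 0.0], (20, 1))
    green = np.tile([0.0, 0.0], (20, 1))
    red[5:15] = np.nan
    pose = head_pose(_tracking(red, green), max_gap=5)
    assert not pose.valid[5:15].any()
    assert pose.valid[:5].all() and pose.valid[15:].all()


# ---------------------------------------------------------------------------
# per-frame series

def test_uniform_circular_motion_about_lever():
    fr, radius, omega = 30.0, 100.0, 0.5
    t = np.arange(0, 8, 1 / fr)
    pos = radius * np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    pose = make_pose(pos[:, 0], pos[:, 1])
    series = kinematic_series(pose, lever_xy=(0.0, 0.0))
    mid = series.iloc[10:-10]
    assert np.nanmax(np.abs(mid["radial_velocity"])) < 0.1
    assert np.allclose(np.abs(mid["angular_velocity"]), omega, rtol=1e-3)
    assert np.allclose(mid["speed"], radius * omega, rtol=1e-3)


def test_straight_approach_radial_velocity():
    fr = 30.0
    x = np.arange(300.0, 0.0, -10.0)  # 10 mm/frame = 300 mm/s toward origin
    pose = make_pose(x)
    series = kinematic_series(pose, lever_xy=(0.0, 0.0))
    mid = series.iloc[2:-2]
    assert np.allclose(mid["radial_velocity"], 300.0, rtol=1e-9)
    assert np.allclose(mid["angular_velocity"].dropna(), 0.0, atol=1e-9)


def test_polar_decomposition_identity(rng):
    # speed^2 ~= radial^2 + (distance * angular velocity)^2 on a smooth path
    fr = 30.0
    t = np.arange(0, 4, 1 / fr)
    x = 120 + 80 * np.cos(0.9 * t) + 10 * np.sin(0.23 * t)
    y = 110 + 70 * np.sin(0.8 * t)
    pose = make_pose(x, y)
    lever = (40.0, 60.0)
    series = kinematic_series(pose, lever)
    dist = np.hypot(x - lever[0], y - lever[1])
    idx = np.arange(2, len(t) - 2)
    lhs = series["speed"].to_numpy()[idx] ** 2
    # midpoint distance of each step for the tangential term
    dmid = 0.5 * (dist[1:] + dist[:-1])
    rhs = (
        series["radial_velocity"].to_numpy()[idx] ** 2
        + (dmid[idx - 1] * series["angular_velocity"].to_numpy()[idx]) ** 2
    )
    assert np.allclose(lhs, rhs, rtol=0.01)


# ---------------------------------------------------------------------------
# movement features

def test_straight_path_features_closed_form():
    x = np.arange(10.0) * 10.0  # 10 mm/frame at 30 Hz
    pose = make_pose(x)
    f = movement_features(pose, 0.0, 9 / 30, lever_xy=(1000.0, 0.0))
    assert f["speed_mean"] == pytest.approx(300.0)
    assert f["path_length"] == pytest.approx(90.0)
    assert f["path_efficiency"] == pytest.approx(1.0)
    assert f["max_path_deviation"] == pytest.approx(0.0, abs=1e-12)
    assert f["net_heading_change"] == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(f["turn_efficiency"])  # undefined for zero net turn


def test_right_angle_path_efficiency():
    xs = np.concatenate([np.linspace(0, 30, 7), np.full(8, 30.0)])
    ys = np.concatenate([np.zeros(7), np.linspace(5, 40, 8)])
    # construct exact 3-4-5: legs 30 and 40
    xs = np.concatenate([np.linspace(0, 30, 4), np.full(4, 30.0)])
    ys = np.concatenate([np.zeros(4), np.linspace(10, 40, 4)])
    pose = make_pose(xs, ys)
    f = movement_features(pose, 0.0, (len(xs) - 1) / 30, lever_xy=(0.0, 0.0))
    assert f["path_length"] == pytest.approx(70.0)
    assert f["path_efficiency"] == pytest.approx(50.0 / 70.0)


def test_semicircle_and_quarter_turn_geometry():
    theta = np.linspace(0, np.pi, 61)
    pose = make_pose(50 * np.cos(theta), 50 * np.sin(theta))
    f = movement_features(pose, 0.0, 60 / 30, lever_xy=(0.0, 0.0))
    assert f["path_efficiency"] == pytest.approx(2 / np.pi, rel=1e-3)

    # monotone quarter-turn heading sweep -> turn efficiency 1
    heading = np.linspace(0, np.pi / 2, 31)
    pose2 = PoseSeries(
        position=np.column_stack([np.linspace(0, 30, 31), np.linspace(0, 10, 31)]),
        heading=heading,
        valid=np.ones(31, bool),
        frame_rate=30.0,
    )
    f2 = movement_features(pose2, 0.0, 1.0, lever_xy=(100.0, 100.0))
    assert f2["turn_efficiency"] == pytest.approx(1.0, abs=1e-9)
    assert f2["net_heading_change"] == pytest.approx(np.pi / 2, abs=1e-9)


def features_oracle(pose, start_t, end_t, lever, fr=30.0):
    """Literal recomputation of every feature from its definition."""
    i0 = int(np.ceil(start_t * fr - 1e-9))
    i1 = int(np.floor(end_t * fr + 1e-9))
    pts = pose.position[i0 : i1 + 1]
    hd = pose.heading[i0 : i1 + 1]
    lever = np.asarray(lever, float)
    disp = [float(np.hypot(*(pts[i] - pts[i - 1]))) for i in range(1, len(pts))]
    speed = [d * fr for d in disp]
    dist = [float(np.hypot(*(p - lever))) for p in pts]
    radial = [-(dist[i] - dist[i - 1]) * fr for i in range(1, len(pts))]
    theta = [float(np.arctan2(p[1] - lever[1], p[0] - lever[0])) for p in pts]
    ang = [abs(wrap_angle(theta[i] - theta[i - 1])) * fr for i in range(1, len(pts))]
    hstep = [float(wrap_angle(hd[i] - hd[i - 1])) for i in range(1, len(pts))]
    out = {}
    out["speed_mean"] = np.mean(speed)
    out["speed_max"] = np.max(speed)
    out["speed_sd"] = np.std(speed, ddof=1)
    out["radial_velocity_mean"] = np.mean(radial)
    out["radial_velocity_max"] = np.max(radial)
    out["radial_velocity_sd"] = np.std(radial, ddof=1)
    out["angular_velocity_mean"] = np.mean(ang)
    out["angular_velocity_max"] = np.max(ang)
    out["angular_velocity_sd"] = np.std(ang, ddof=1)
    out["move_duration"] = end_t - start_t
    out["path_length"] = sum(disp)
    times = [(i0 + 1 + i) / fr for i in range(len(speed))]
    out["latency_to_max_speed"] = times[int(np.argmax(speed))] - start_t
    accel = [(speed[i] - speed[i - 1]) * fr for i in range(1, len(speed))]
    out["latency_to_max_accel"] = times[1 + int(np.argmax(accel))] - start_t
    a, b = pts[0], pts[-1]
    ab = b - a
    devs = []
    for p in pts:
        if np.dot(ab, ab) < 1e-24:
            devs.append(float(np.hypot(*(p - a))))
            continue
        u = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
        devs.append(float(np.hypot(*(p - (a + u * ab)))))
    out["max_path_deviation"] = max(devs)
    out["path_efficiency"] = float(np.hypot(*ab)) / sum(disp)
    net = sum(hstep)
    out["net_heading_change"] = net
    out["turn_efficiency"] = sum(abs(h) for h in hstep) / abs(net) if abs(net) >= 1e-3 else np.nan
    return out


def test_features_equal_literal_recomputation(rng):
    for _ in range(40):
        n = int(rng.integers(8, 60))
        pos = np.cumsum(rng.normal(0, 6, (n, 2)), axis=0) + 100
        heading = np.cumsum(rng.normal(0, 0.2, n))
        pose = PoseSeries(pos, wrap_angle(heading), np.ones(n, bool), 30.0)
        start, end = 0.0, (n - 1) / 30.0
        lever = rng.uniform(0, 200, 2)
        got = movement_features(pose, start, end, lever)
        expect = features_oracle(pose, start, end, lever)
        for k, v in expect.items():
            if np.isnan(v):
                assert np.isnan(got[k]), k
            else:
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k


def test_features_invariant_under_rigid_motions(rng):
    n = 40
    pos = np.cumsum(rng.normal(0, 5, (n, 2)), axis=0) + 100
    heading = wrap_angle(np.cumsum(rng.normal(0, 0.2, n)))
    lever = np.array([40.0, 60.0])
    base = movement_features(PoseSeries(pos, heading, np.ones(n, bool), 30.0), 0, (n - 1) / 30, lever)
    phi, shift = 1.1, np.array([55.0, -20.0])
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pos2 = pos @ R.T + shift
    transformed = movement_features(
        PoseSeries(pos2, wrap_angle(heading + phi), np.ones(n, bool), 30.0),
        0,
        (n - 1) / 30,
        lever @ R.T + shift,
    )
    for k in MOVEMENT_VARIABLES:
        if k == "movement_onset_latency":
            continue
        a, b = base[k], transformed[k]
        if np.isnan(a):
            assert np.isnan(b), k
        else:
            assert b == pytest.approx(a, rel=1e-9, abs=1e-9), k


def test_turn_efficiency_at_least_one_when_defined(rng):
    for _ in range(30):
        n = 25
        heading = wrap_angle(np.cumsum(rng.normal(0, 0.4, n)))
        pos = np.cumsum(rng.normal(0, 5, (n, 2)), axis=0)
        f = movement_features(PoseSeries(pos, heading, np.ones(n, bool), 30.0), 0, (n - 1) / 30, (0, 0))
        te = f["turn_efficiency"]
        if not np.isnan(te):
            assert te >= 1.0 - 1e-12
        assert 0 < f["path_efficiency"] <= 1.0 + 1e-12


def test_too_few_valid_frames_flagged_incomplete():
    pose = make_pose(np.arange(10.0))
    pose.valid[2:9] = False
    f = movement_features(pose, 0.0, 9 / 30, lever_xy=(0, 0))
    assert all(np.isnan(v) for k, v in f.items() if k != "movement_onset_latency")


# ---------------------------------------------------------------------------
# state features

def _events(rows):
    return EventLog(pd.DataFrame(rows, columns=["time_s", "kind", "payload"]))


def test_state_distance_orientation_and_elapsed_times():
    n = 3100
    pose = PoseSeries(
        position=np.zeros((n, 2)),
        heading=np.zeros(n),  # facing +x
        valid=np.ones(n, bool),
        frame_rate=30.0,
    )
    ev = _events([(90.0, "reward", ""), (95.0, "DS_on", ""), (96.0, "DS_off", "")])
    f = state_features(pose, ev, cue_t=100.0, lever_xy=(30.0, 40.0))
    assert f["lever_distance"] == pytest.approx(50.0)
    assert f["time_since_reward"] == pytest.approx(10.0)
    assert f["time_since_cue"] == pytest.approx(5.0)
    assert np.isnan(f["time_since_press"])  # no prior press

    f2 = state_features(pose, ev, cue_t=100.0, lever_xy=(0.0, 50.0))
    assert f2["orientation_to_lever"] == pytest.approx(np.pi / 2)
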