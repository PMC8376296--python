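"""Head pose and approach-movement kinematics.

The head is tracked with two LEDs.  Head *position* is the LED midpoint and
*heading* is the direction of the rear-to-front LED vector, wrapped to
(-pi, pi].  From the pose we derive, in lever-centered polar coordinates,
the radial velocity toward the lever (positive = approaching) and the
angular velocity of the head about the lever, plus plain speed and heading
increments.  Per-trial feature vectors collect the movement variables
(speed, radial/angular velocity statistics, duration, path length,
efficiency measures, heading change, latencies) over the cued approach
window, and the behavioral-state variables sampled at cue onset (distance
and egocentric bearing to the lever, elapsed times since the last reward,
lever press, and cue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventLog, TrackingSeries

TURN_NET_EPS = 1e-3  # rad; below this the net heading change is treated as zero

#: canonical movement-variable order (18 variables)
MOVEMENT_VARIABLES = [
    "radial_velocity_mean",
    "radial_velocity_max",
    "radial_velocity_sd",
    "speed_mean",
    "speed_sd",
    "speed_max",
    "move_duration",
    "path_length",
    "latency_to_max_speed",
    "latency_to_max_accel",
    "max_path_deviation",
    "turn_efficiency",
    "angular_velocity_sd",
    "angular_velocity_max",
    "angular_velocity_mean",
    "net_heading_change",
    "path_efficiency",
    "movement_onset_latency",
]

#: behavioral-state variables measured at cue onset
STATE_VARIABLES = [
    "lever_distance",
    "time_since_reward",
    "time_since_press",
    "time_since_cue",
    "orientation_to_lever",
]


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


@dataclass
class PoseSeries:
    """Per-frame head position (mm) and heading (rad), with validity mask."""

    position: np.ndarray  # (n, 2)
    heading: np.ndarray  # (n,)
    valid: np.ndarray  # (n,) bool
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.heading)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def _interp_gaps(values: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs of length <= max_gap (per column).

    Returns (filled, valid) where valid marks frames that are observed or
    interpolated across a short interior gap.
    """
    v = values.copy()
    n = len(v)
    finite = np.isfinite(values).all(axis=1)
    valid = finite.copy()
    idx = np.flatnonzero(finite)
    if idx.size < 2:
        return v, valid
    # iterate over gap runs between consecutive observed frames
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        if gap <= max_gap:
            frac = (np.arange(1, gap + 1) / (gap + 1))[:, None]
            v[a + 1 : b] = values[a] + frac * (values[b] - values[a])
            valid[a + 1 : b] = True
    return v, valid


def head_pose(tracking: TrackingSeries, front_led: str = "red", max_gap: int = 5) -> PoseSeries:
    """Derive head position and heading from the two LEDs.

    Single-LED or short both-LED gaps (<= ``max_gap`` frames) are linearly
    interpolated per coordinate; longer gaps stay invalid.  Leading/trailing
    missing frames are never extrapolated.
    """
    if front_led not in ("red", "green"):
        raise ValueError("front_led must be 'red' or 'green'")
    front = tracking.red_xy if front_led == "red" else tracking.green_xy
    rear = tracking.green_xy if front_led == "red" else tracking.red_xy
    front_f, front_ok = _interp_gaps(front, max_gap)
    rear_f, rear_ok = _interp_gaps(rear, max_gap)
    valid = front_ok & rear_ok
    position = 0.5 * (front_f + rear_f)
    delta = front_f - rear_f
    heading = np.arctan2(delta[:, 1], delta[:, 0])
    heading = wrap_angle(heading)
    position = np.where(valid[:, None], position, np.nan)
    heading = np.where(valid, heading, np.nan)
    return PoseSeries(position=position, heading=heading, valid=valid, frame_rate=tracking.frame_rate)


def kinematic_series(pose: PoseSeries, lever_xy, frame_rate: float | None = None) -> pd.DataFrame:
    """Per-frame speed, radial/angular velocity about the lever, heading steps.

    Quantities at frame ``t`` describe the step from frame ``t-1`` to ``t``;
    frame 0 and frames adjacent to invalid pose samples are NaN.  Radial
    velocity is positive when approaching the lever.  A frame exactly at the
    lever position makes the polar angle (hence angular velocity) undefined
    for the adjacent steps.
    """
    fr = pose.frame_rate if frame_rate is None else frame_rate
    lever = np.asarray(lever_xy, dtype=float)
    pos = pose.position
    n = pose.n_frames
    out = pd.DataFrame(
        index=np.arange(n),
        columns=["speed", "radial_velocity", "angular_velocity", "heading_step"],
        dtype=float,
    )
    if n < 2:
        return out
    step_ok = pose.valid[1:] & pose.valid[:-1]
    disp = pos[1:] - pos[:-1]
    speed = np.hypot(disp[:, 0], disp[:, 1]) * fr
    rel = pos - lever
    dist = np.hypot(rel[:, 0], rel[:, 1])
    radial = -(dist[1:] - dist[:-1]) * fr
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    ang = wrap_angle(theta[1:] - theta[:-1]) * fr
    at_lever = dist < 1e-12
    ang_ok = step_ok & ~at_lever[1:] & ~at_lever[:-1]
    hstep = wrap_angle(pose.heading[1:] - pose.heading[:-1])
    out.iloc[1:, 0] = np.where(step_ok, speed, np.nan)
    out.iloc[1:, 1] = np.where(step_ok, radial, np.nan)
    out.iloc[1:, 2] = np.where(ang_ok, ang, np.nan)
    out.iloc[1:, 3] = np.where(step_ok, hstep, np.nan)
    return out


def _point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        d = points - a
        return np.hypot(d[:, 0], d[:, 1])
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = points - proj
    return np.hypot(d[:, 0], d[:, 1])


def movement_features(
    pose: PoseSeries,
    start_t: float,
    end_t: float,
    lever_xy,
    onset_latency: float = np.nan,
    min_frames: int = 3,
) -> dict[str, float]:
    """The 18 movement variables over the window [start_t, end_t].

    Angular-velocity statistics are computed on the magnitude of the angular
    velocity about the lever; radial-velocity statistics on the signed value.
    Turn efficiency is NaN (undefined) when the net heading change is below
    ``TURN_NET_EPS``.  Returns all-NaN (with ``complete=False`` semantics)
    when fewer than ``min_frames`` valid frames fall in the window.
    """
    if not start_t < end_t:
        raise ValueError("start_t must precede end_t")
    fr = pose.frame_rate
    i0 = int(np.ceil(start_t * fr - 1e-9))
    i1 = int(np.floor(end_t * fr + 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, pose.n_frames - 1)
    feats = {name: np.nan for name in MOVEMENT_VARIABLES}
    feats["movement_onset_latency"] = onset_latency
    if i1 - i0 + 1 < min_frames:
        return feats
    idx = np.arange(i0, i1 + 1)
    valid = pose.valid[idx]
    if valid.sum() < min_frames or not (valid[0] and valid[-1]):
        return feats

    window_pose = PoseSeries(
        position=pose.position[idx],
        heading=pose.heading[idx],
        valid=valid,
        frame_rate=fr,
    )
    series = kinematic_series(window_pose, lever_xy)
    # steps within the window: rows 1.. of the slice
    speed = series["speed"].to_numpy()[1:]
    radial = series["radial_velocity"].to_numpy()[1:]
    ang = np.abs(series["angular_velocity"].to_numpy()[1:])
    hstep = series["heading_step"].to_numpy()[1:]
    ok = np.isfinite(speed)
    if ok.sum() < min_frames - 1:
        return feats
    speed_v = speed[ok]
    radial_v = radial[ok]
    ang_v = ang[np.isfinite(ang)]
    hstep_v = hstep[np.isfinite(hstep)]

    feats["speed_mean"] = float(np.mean(speed_v))
    feats["speed_max"] = float(np.max(speed_v))
    feats["speed_sd"] = float(np.std(speed_v, ddof=1)) if speed_v.size > 1 else np.nan
    feats["radial_velocity_mean"] = float(np.mean(radial_v))
    feats["radial_velocity_max"] = float(np.max(radial_v))
    feats["radial_velocity_sd"] = (
        float(np.std(radial_v, ddof=1)) if radial_v.size > 1 else np.nan
    )
    if ang_v.size:
        feats["angular_velocity_mean"] = float(np.mean(ang_v))
        feats["angular_velocity_max"] = float(np.max(ang_v))
        feats["angular_velocity_sd"] = (
            float(np.std(ang_v, ddof=1)) if ang_v.size > 1 else np.nan
        )

    feats["move_duration"] = float(end_t - start_t)
    path_length = float(np.sum(speed_v)) / fr
    feats["path_length"] = path_length

    times = idx[1:][ok] / fr
    feats["latency_to_max_speed"] = float(times[np.argmax(speed_v)] - start_t)
    accel = np.diff(speed_v) * fr
    if accel.size:
        feats["latency_to_max_accel"] = float(times[1:][np.argmax(accel)] - start_t)

    pts = pose.position[idx][valid]
    a, b = pts[0], pts[-1]
    feats["max_path_deviation"] = float(np.max(_point_segment_distance(pts, a, b)))
    straight = float(np.hypot(*(b - a)))
    feats["path_efficiency"] = straight / path_length if path_length > 0 else np.nan

    net = float(np.sum(hstep_v))  # cumulative unwrapped; |net| may exceed pi
    feats["net_heading_change"] = net
    total_turn = float(np.sum(np.abs(hstep_v)))
    feats["turn_efficiency"] = total_turn / abs(net) if abs(net) >= TURN_NET_EPS else np.nan
    return feats


def state_features(
    pose: PoseSeries, events: EventLog, cue_t: float, lever_xy
) -> dict[str, float]:
    """Behavioral-state variables at cue onset.

    Elapsed times are measured from the most recent *prior* reward, active
    lever press, and cue onset (DS or NS); NaN when no prior event exists.
    Orientation to the lever is the absolute egocentric bearing in [0, pi].
    """
    fr = pose.frame_rate
    frame = int(round(cue_t * fr))
    feats = {name: np.nan for name in STATE_VARIABLES}
    if frame < 0 or frame >= pose.n_frames or not pose.valid[frame]:
        return feats
    lever = np.asarray(lever_xy, dtype=float)
    rel = lever - pose.position[frame]
    feats["lever_distance"] = float(np.hypot(*rel))
    bearing = np.arctan2(rel[1], rel[0])
    feats["orientation_to_lever"] = float(abs(wrap_angle(bearing - pose.heading[frame])))

    def last_before(times: np.ndarray) -> float:
        prior = times[times < cue_t - 1e-9]
        return float(cue_t - prior[-1]) if prior.size else np.nan

    feats["time_since_reward"] = last_before(np.sort(events.times("reward")))
    feats["time_since_press"] = last_before(np.sort(events.times("active_press")))
    cues = np.sort(np.concatenate([events.times("DS_on"), events.times("NS_on")]))
    feats["time_since_cue"] = last_before(cues)
    return feats
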