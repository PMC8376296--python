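"""Synthetic session generator with exported ground truth.

Generates complete session bundles — cue schedule, head-tracking behavior,
and spike trains — whose statistical structure matches what the analysis
assumes, so the full pipeline can be exercised against known generative
parameters:

* **Cue schedule**: DS and NS cues interleaved with exponentially
  distributed intertrial intervals (mean 30 s, measured from cue offset to
  the next onset) approximating a constant hazard of cue onset; DS
  terminates at the lever press or 10 s, NS is a fixed 10 s.
* **Behavior**: between trials the head alternates quiet stillness,
  small-amplitude fidgeting, and roaming locomotion toward random waypoints
  (so the still-at-cue filter sees both outcomes); on responded trials,
  after a lognormal latency the head executes a curved (quadratic Bezier)
  approach to the lever with a half-sine speed profile and per-frame
  displacement jitter, presses, then visits the reward receptacle.  The two
  LEDs are placed astride the heading axis with isotropic Gaussian tracking
  noise (default 1.5 mm at 30 frames/s).
* **Spikes**: each neuron is an inhomogeneous Poisson process: constant
  baseline plus, for excited neurons, a two-phase cue-evoked kernel (early
  component 40-180 ms, late 180-400 ms) whose trial gain is log-linear in
  the trial's *noise-free* movement/state features:
  ``gain = exp(sum_v beta_v * (v - center_v))``.  NS trials scale the gain
  by an NS ratio; an optional infusion epoch multiplies post-infusion
  evoked gain by an attenuation factor.

All randomness flows from one master seed through named substreams
(schedule / behavior / spikes); regeneration is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    EventLog,
    SessionBundle,
    SessionManifest,
    SpikeTrain,
    TrackingSeries,
)
from . import kinematics as km


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic session.

    Defaults emulate a 3-h rat discriminative-stimulus session: mean 30-s
    exponential ITIs, 10-s cues, ~92% DS response ratio, lognormal movement
    latencies around 0.8 s, approach peak speeds of a few hundred mm/s, and
    1.5-mm tracking noise at 30 frames/s.
    """

    # schedule
    duration_s: float = 10_800.0
    mean_iti_s: float = 30.0
    cue_length_s: float = 10.0
    p_respond_ds: float = 0.92
    p_respond_ns: float = 0.10
    schedule_mode: str = "single"  # 'single' labeled stream | 'dual' streams
    latency_median_s: float = 0.8
    latency_sigma: float = 0.5
    approach_peak_speed_median: float = 420.0  # mm/s
    approach_peak_speed_sigma: float = 0.25
    approach_min_duration_s: float = 0.45

    # geometry / tracking
    arena_mm: tuple[float, float] = (300.0, 250.0)
    lever_xy_mm: tuple[float, float] = (40.0, 60.0)
    receptacle_xy_mm: tuple[float, float] = (40.0, 140.0)
    frame_rate: float = 30.0
    tracking_noise_mm: float = 1.5
    led_separation_mm: float = 40.0

    # roaming model
    still_mean_s: float = 4.5
    move_mean_s: float = 3.0
    fidget_prob: float = 0.2  # fraction of still segments with small head wiggles
    fidget_step_mm: float = 2.5
    roam_speed_range: tuple[float, float] = (120.0, 300.0)
    speed_jitter: float = 0.45  # lognormal sigma of per-frame displacement jitter
    curvature_noise: float = 0.25  # Bezier control offset, fraction of distance
    consume_s: float = 3.0

    # neuron population
    n_neurons: int = 40
    frac_excited: float = 0.4
    baseline_rate_range: tuple[float, float] = (2.0, 15.0)
    early_amp_range: tuple[float, float] = (15.0, 40.0)  # Hz above baseline at gain 1
    late_amp_range: tuple[float, float] = (5.0, 15.0)
    ns_gain: float = 0.6
    couplings: dict = field(
        default_factory=lambda: {
            # scaled so population mean IDR Firing Differences land in the
            # +-20-35% range reported for real cue-excited populations
            "radial_velocity_max": 0.00075,  # per mm/s
            "path_efficiency": 1.0,  # per unit
            "lever_distance": -0.0019,  # per mm
        }
    )
    coupling_centers: dict = field(
        default_factory=lambda: {
            "radial_velocity_max": 300.0,
            "path_efficiency": 0.85,
            "lever_distance": 140.0,
        }
    )
    couplings_late: Optional[dict] = None  # None -> same as `couplings`
    gain_cap: float = 8.0
    max_rate_hz: float = 400.0

    # optional infusion epoch
    infusion_time_s: Optional[float] = None
    infusion_condition: Optional[str] = None
    attenuation: float = 1.0

    subject_id: str = "rat1"
    session_id: str = "synthetic"

    def validate(self) -> None:
        assert 0 <= self.p_respond_ds <= 1 and 0 <= self.p_respond_ns <= 1
        assert self.duration_s > self.cue_length_s
        assert 0 < self.attenuation <= 1.0
        assert self.frame_rate > 0 and self.mean_iti_s > 0


@dataclass
class TrialPlan:
    index: int
    onset: float
    cue_type: str  # DS | NS
    respond: bool
    latency: float  # drawn movement-onset latency (s after cue)
    peak_speed: float  # drawn peak approach speed (mm/s)
    approach_duration: float  # provisional estimate; realized depends on distance
    offset: float  # provisional cue offset


@dataclass
class CueSchedule:
    trials: list[TrialPlan]
    itis: np.ndarray  # drawn intertrial gaps (s)
    deferrals: int = 0


@dataclass
class GroundTruth:
    trials: pd.DataFrame
    neurons: pd.DataFrame
    bouts: pd.DataFrame  # true movement intervals (roam + approach)
    itis: np.ndarray
    config: SimulationConfig


def _lognormal(rng, median, sigma, size=None):
    return np.exp(np.log(median) + sigma * rng.standard_normal(size))


def generate_cue_schedule(config: SimulationConfig, seed) -> CueSchedule:
    """Draw the cue schedule.

    Single mode (default): one interleaved stream; each gap from the previous
    cue's offset to the next onset is exponential with mean ``mean_iti_s``
    and the cue is DS or NS with equal probability.  Dual mode: independent
    exponential *inter-onset* streams per cue type (mean ``mean_iti_s``
    each), later cues deferred past an ongoing cue (deferrals counted).
    """
    rng = np.random.default_rng(seed)
    config.validate()
    trials: list[TrialPlan] = []
    itis: list[float] = []
    deferrals = 0

    def plan(idx, onset, cue_type):
        p = config.p_respond_ds if cue_type == "DS" else config.p_respond_ns
        respond = bool(rng.random() < p)
        latency = float(_lognormal(rng, config.latency_median_s, config.latency_sigma))
        peak = float(
            _lognormal(rng, config.approach_peak_speed_median, config.approach_peak_speed_sigma)
        )
        # provisional duration for a typical ~150-mm approach (half-sine profile)
        dur = max(150.0 * np.pi / (2.0 * peak), config.approach_min_duration_s)
        press = latency + dur
        if press >= config.cue_length_s:
            respond = False
        if cue_type == "DS":
            offset = onset + (press if respond else config.cue_length_s)
        else:
            offset = onset + config.cue_length_s
        return TrialPlan(idx, onset, cue_type, respond, latency, peak, dur, offset)

    horizon = config.duration_s - config.cue_length_s - config.consume_s - 2.0
    if config.schedule_mode == "single":
        t_off = 0.0
        idx = 0
        while True:
            gap = float(rng.exponential(config.mean_iti_s))
            onset = t_off + gap
            if onset > horizon:
                break
            itis.append(gap)
            cue_type = "DS" if rng.random() < 0.5 else "NS"
            tp = plan(idx, onset, cue_type)
            trials.append(tp)
            t_off = tp.offset
            idx += 1
    elif config.schedule_mode == "dual":
        onsets = []
        for cue_type in ("DS", "NS"):
            t = 0.0
            while True:
                gap = float(rng.exponential(config.mean_iti_s))
                t += gap
                if t > horizon:
                    break
                itis.append(gap)
                onsets.append((t, cue_type))
        onsets.sort()
        t_off = 0.0
        for idx, (onset, cue_type) in enumerate(onsets):
            if onset < t_off:
                onset = t_off
                deferrals += 1
            if onset > horizon:
                break
            tp = plan(idx, onset, cue_type)
            tp.onset = onset
            trials.append(tp)
            t_off = tp.offset
    else:
        raise ValueError("schedule_mode must be 'single' or 'dual'")
    return CueSchedule(trials=trials, itis=np.asarray(itis), deferrals=deferrals)


# ---------------------------------------------------------------------------
# behavior


def _bezier_path(p0, p1, n_steps, curve_frac, rng):
    """Quadratic Bezier from p0 to p1 sampled at arc-length-uniform points."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    delta = p1 - p0
    dist = float(np.hypot(*delta))
    perp = np.array([-delta[1], delta[0]]) / max(dist, 1e-9)
    ctrl = 0.5 * (p0 + p1) + perp * curve_frac * dist * rng.standard_normal()
    u = np.linspace(0, 1, max(4 * n_steps, 64))
    pts = (
        (1 - u)[:, None] ** 2 * p0
        + 2 * (u * (1 - u))[:, None] * ctrl
        + (u[:, None] ** 2) * p1
    )
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0], np.cumsum(seg)])
    return pts, s  # dense points and cumulative arc length


def _sample_profile(total_len, n_steps, jitter, rng, attack_frac=0.15):
    """Cumulative arc-length per frame: trapezoidal speed profile with jitter.

    Speed ramps up over the first ``attack_frac`` of the movement, cruises,
    and ramps down symmetrically — a brisk initiation like real locomotor
    onsets, which a sliding-SD movement detector keys on.
    """
    fa = min(max(attack_frac, 1.0 / max(n_steps, 2)), 0.45)
    u = (np.arange(n_steps) + 0.5) / n_steps
    speed = np.minimum(np.minimum(u / fa, (1 - u) / fa), 1.0)
    inc = np.maximum(speed, 1e-6)
    if jitter > 0 and inc.size:
        inc = inc * np.exp(jitter * rng.standard_normal(inc.size))
    s = np.concatenate([[0], np.cumsum(inc)])
    return s / s[-1] * total_len


class _BehaviorBuilder:
    """Sequential frame-level builder of the noise-free head trajectory."""

    def __init__(self, config: SimulationConfig, rng):
        self.cfg = config
        self.rng = rng
        self.fr = config.frame_rate
        self.n_frames = int(round(config.duration_s * config.frame_rate)) + 1
        self.pos = np.zeros((self.n_frames, 2))
        self.heading = np.zeros(self.n_frames)
        self.frame = 0
        w, h = config.arena_mm
        self.pos[0] = (w * 0.6, h * 0.5)
        self.true_moves: list[tuple[float, float, str]] = []

    # -- segment fills ------------------------------------------------------
    def _write(self, f0, pts, headings):
        f1 = f0 + len(pts)
        self.pos[f0:f1] = pts
        self.heading[f0:f1] = headings
        self.frame = f1

    def hold_still(self, n: int, fidget: bool = False):
        if n <= 0:
            return
        f0 = self.frame
        if fidget:
            self.true_moves.append((f0 / self.fr, (f0 + n - 1) / self.fr, "fidget"))
        anchor = self.pos[f0 - 1] if f0 else self.pos[0]
        h = self.heading[f0 - 1] if f0 else 0.0
        if not fidget:
            pts = np.repeat(anchor[None, :], n, axis=0)
        else:
            steps = self.cfg.fidget_step_mm * self.rng.standard_normal((n, 2))
            pts = np.empty((n, 2))
            p = anchor.copy()
            for i in range(n):
                p = p + steps[i] + 0.25 * (anchor - p)
                pts[i] = p
        self._write(f0, pts, np.full(n, h))

    def travel(self, target, duration_s: float, label: str, speed_cap=None):
        """Curved move from the current position to target over duration."""
        n = max(int(round(duration_s * self.fr)), 2)
        f0 = self.frame
        if f0 + n > self.n_frames:
            n = self.n_frames - f0
            if n <= 0:
                return
        start = self.pos[f0 - 1] if f0 else self.pos[0]
        dense, s = _bezier_path(start, target, n, self.cfg.curvature_noise, self.rng)
        total = s[-1]
        prog = _sample_profile(total, n, self.cfg.speed_jitter, self.rng)[1:]
        pts = np.empty((n, 2))
        for i, sv in enumerate(prog):
            k = np.searchsorted(s, sv)
            k = min(max(k, 1), len(s) - 1)
            w = (sv - s[k - 1]) / max(s[k] - s[k - 1], 1e-12)
            pts[i] = dense[k - 1] + w * (dense[k] - dense[k - 1])
        disp = np.diff(np.vstack([start, pts]), axis=0)
        h_prev = self.heading[f0 - 1] if f0 else 0.0
        headings = np.empty(n)
        for i in range(n):
            if np.hypot(*disp[i]) > 1e-6:
                target_h = math.atan2(disp[i][1], disp[i][0])
                # first-order heading lag
                z = 0.45 * np.exp(1j * h_prev) + 0.55 * np.exp(1j * target_h)
                h_prev = float(np.angle(z))
            headings[i] = h_prev
        self._write(f0, pts, headings)
        self.true_moves.append((f0 / self.fr, (f0 + n - 1) / self.fr, label))

    def roam_until(self, t_end: float, finish_moves: bool = False):
        """Alternate still/move segments until t_end.

        With ``finish_moves`` a move segment begun before ``t_end`` runs to
        its natural boundary (possibly past ``t_end``), emulating an animal
        completing its movement through a cue onset.
        """
        cfg, rng = self.cfg, self.rng
        f_end = min(int(round(t_end * self.fr)), self.n_frames)
        w, h = cfg.arena_mm
        while self.frame < f_end:
            still_dur = rng.exponential(cfg.still_mean_s)
            n_still = int(round(still_dur * self.fr))
            n_still = min(n_still, f_end - self.frame)
            self.hold_still(n_still, fidget=bool(rng.random() < cfg.fidget_prob))
            if self.frame >= f_end:
                break
            move_dur = max(rng.exponential(cfg.move_mean_s), 0.4)
            target = np.array(
                [rng.uniform(25, w - 25), rng.uniform(25, h - 25)]
            )
            start = self.pos[self.frame - 1] if self.frame else self.pos[0]
            dist = float(np.hypot(*(target - start)))
            speed = rng.uniform(*cfg.roam_speed_range)
            dur = min(move_dur, max(dist / speed, 0.3))
            remaining = (min(f_end, self.n_frames) - self.frame) / self.fr
            hard_remaining = (self.n_frames - self.frame) / self.fr
            limit = hard_remaining if finish_moves else remaining
            if dur > limit:
                # shorten the move toward a proportionally nearer waypoint
                frac = max(limit, 2 / self.fr) / dur
                target = start + (target - start) * frac
                dur = max(limit, 2 / self.fr)
                if self.frame + int(round(dur * self.fr)) > self.n_frames:
                    break
            self.travel(target, dur, "roam")


def generate_behavior(schedule: CueSchedule, config: SimulationConfig, seed):
    """Synthesize tracking, behavioral events, and per-trial ground truth.

    Returns (tracking, events_df, trial_truth_df, bouts_df).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    builder = _BehaviorBuilder(cfg, rng)
    fr = cfg.frame_rate
    events: list[tuple[float, str, str]] = []
    truth_rows: list[dict] = []
    lever = np.asarray(cfg.lever_xy_mm)
    receptacle = np.asarray(cfg.receptacle_xy_mm)

    for tp in schedule.trials:
        onset = tp.onset
        # roam up to the cue; if mid-move at cue onset, finish that move
        if builder.frame / fr < onset:
            builder.roam_until(onset, finish_moves=True)
        cue_kind = f"{tp.cue_type}_on"
        events.append((onset, cue_kind, ""))
        moving_at_cue = any(
            a <= onset <= b
            for a, b, kind in builder.true_moves[-3:]
            if kind != "fidget"
        )

        press_t = np.nan
        approach_start_t = np.nan
        realized_respond = False
        if tp.respond:
            t_free = builder.frame / fr  # after finishing any ongoing move
            start_t = max(onset + tp.latency, t_free)
            f_start = int(round(start_t * fr))
            builder.hold_still(f_start - builder.frame)
            approach_start_t = builder.frame / fr
            dist = float(np.hypot(*(lever - builder.pos[max(builder.frame - 1, 0)])))
            # half-sine profile: duration so the peak speed matches the draw
            # (1.05 absorbs the extra arc length of the curved path)
            dur = max(
                1.05 * dist * np.pi / (2.0 * tp.peak_speed),
                cfg.approach_min_duration_s,
            )
            builder.travel(lever, dur, "approach")
            press_frame = builder.frame - 1
            press_t = press_frame / fr
            if press_t <= onset + cfg.cue_length_s:
                realized_respond = True
                events.append((press_t, "active_press", ""))

        # cue offset
        if tp.cue_type == "DS":
            offset = press_t if realized_respond else onset + cfg.cue_length_s
        else:
            offset = onset + cfg.cue_length_s
        events.append((offset, f"{tp.cue_type}_off", ""))

        if realized_respond and tp.cue_type == "DS":
            events.append((press_t, "reward", ""))
            dist = float(np.hypot(*(receptacle - builder.pos[builder.frame - 1])))
            travel_dur = max(dist / 250.0, 0.3)
            builder.travel(receptacle, travel_dur, "to_port")
            entry_t = (builder.frame - 1) / fr
            events.append((entry_t, "port_entry", ""))
            builder.hold_still(int(round(cfg.consume_s * fr)))

        truth_rows.append(
            {
                "trial_id": tp.index,
                "cue_type": tp.cue_type,
                "onset": onset,
                "offset": offset,
                "responded": realized_respond,
                "moving_at_cue": bool(moving_at_cue),
                "movement_start": approach_start_t,
                "movement_end": press_t,
                "latency": approach_start_t - onset if tp.respond else np.nan,
            }
        )

    builder.roam_until(cfg.duration_s)
    if builder.frame < builder.n_frames:
        builder.hold_still(builder.n_frames - builder.frame)

    # noise-free pose -> ground-truth kinematic features per responded trial
    clean_pose = km.PoseSeries(
        position=builder.pos.copy(),
        heading=builder.heading.copy(),
        valid=np.ones(builder.n_frames, dtype=bool),
        frame_rate=fr,
    )
    events_df = pd.DataFrame(sorted(events), columns=["time_s", "kind", "payload"])
    event_log = EventLog(events_df)
    for row in truth_rows:
        feats = {}
        if row["responded"] and np.isfinite(row["movement_start"]):
            feats = km.movement_features(
                clean_pose,
                row["movement_start"],
                row["movement_end"],
                lever,
                onset_latency=row["latency"],
            )
        state = km.state_features(clean_pose, event_log, row["onset"], lever)
        row.update({f"true_{k}": v for k, v in {**feats, **state}.items()})

    trial_truth = pd.DataFrame(truth_rows)

    # emit noisy two-LED tracking
    half = cfg.led_separation_mm / 2.0
    u = np.column_stack([np.cos(builder.heading), np.sin(builder.heading)])
    noise = rng.normal(0.0, cfg.tracking_noise_mm, size=(2, builder.n_frames, 2))
    red = builder.pos + half * u + noise[0]
    green = builder.pos - half * u + noise[1]
    w, h = cfg.arena_mm
    red = np.clip(red, 0, [w, h])
    green = np.clip(green, 0, [w, h])
    tracking = TrackingSeries(
        frame_index=np.arange(builder.n_frames),
        red_xy=np.round(red, 6),
        green_xy=np.round(green, 6),
        frame_rate=fr,
    )
    bouts_df = pd.DataFrame(builder.true_moves, columns=["start_s", "end_s", "kind"])
    return tracking, events_df, trial_truth, bouts_df


# ---------------------------------------------------------------------------
# spikes


def _trial_gain(row: pd.Series, couplings: dict, centers: dict, cap: float) -> float:
    logg = 0.0
    for var, beta in couplings.items():
        v = row.get(f"true_{var}", np.nan)
        center = centers.get(var, 0.0)
        if v is None or not np.isfinite(v):
            v = center  # missing feature contributes no modulation
        logg += beta * (v - center)
    return float(min(np.exp(logg), cap))


def generate_spike_trains(
    trial_truth: pd.DataFrame, config: SimulationConfig, seed
) -> tuple[list[SpikeTrain], pd.DataFrame, np.ndarray]:
    """Simulate the neuron population given the realized trials.

    Returns (spike trains, neuron truth table, per-trial gain matrix of
    shape (n_trials, n_neurons) holding the early-kernel gain factor).
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n = cfg.n_neurons
    baseline = rng.uniform(*cfg.baseline_rate_range, size=n)
    excited = rng.random(n) < cfg.frac_excited
    early_amp = rng.uniform(*cfg.early_amp_range, size=n)
    late_amp = rng.uniform(*cfg.late_amp_range, size=n)
    couplings_late = cfg.couplings_late if cfg.couplings_late is not None else cfg.couplings

    gains_early = np.array(
        [
            _trial_gain(row, cfg.couplings, cfg.coupling_centers, cfg.gain_cap)
            for _, row in trial_truth.iterrows()
        ]
    )
    gains_late = (
        gains_early
        if couplings_late is cfg.couplings
        else np.array(
            [
                _trial_gain(row, couplings_late, cfg.coupling_centers, cfg.gain_cap)
                for _, row in trial_truth.iterrows()
            ]
        )
    )
    ns_mask = (trial_truth["cue_type"] == "NS").to_numpy()
    onsets = trial_truth["onset"].to_numpy(dtype=float)
    post_inf = (
        onsets >= cfg.infusion_time_s if cfg.infusion_time_s is not None else np.zeros(len(onsets), bool)
    )

    trains: list[SpikeTrain] = []
    rows = []
    gain_matrix = np.zeros((len(onsets), n))
    for i in range(n):
        n_base = rng.poisson(baseline[i] * cfg.duration_s)
        base_times = rng.uniform(0.0, cfg.duration_s, n_base)
        if excited[i]:
            # the evoked kernel *replaces* the baseline inside its windows, so
            # the window spike count is exactly log-linear in the features
            prev = np.searchsorted(np.sort(onsets), base_times) - 1
            rel = base_times - np.sort(onsets)[np.clip(prev, 0, None)]
            in_evoked = (prev >= 0) & (rel >= 0.040) & (rel < 0.400)
            times = [base_times[~in_evoked]]
            for j, t0 in enumerate(onsets):
                g = gains_early[j] * (cfg.ns_gain if ns_mask[j] else 1.0)
                gl = gains_late[j] * (cfg.ns_gain if ns_mask[j] else 1.0)
                if post_inf[j]:
                    g *= cfg.attenuation
                    gl *= cfg.attenuation
                gain_matrix[j, i] = g
                for amp, lo, hi in (
                    (early_amp[i] * g, 0.040, 0.180),
                    (late_amp[i] * gl, 0.180, 0.400),
                ):
                    rate = min(amp, cfg.max_rate_hz)
                    k = rng.poisson(rate * (hi - lo))
                    if k:
                        times.append(t0 + rng.uniform(lo, hi, k))
        else:
            times = [base_times]
        st = np.sort(np.concatenate(times))
        st = np.round(st, 6)
        st = st[(st >= 0) & (st <= cfg.duration_s)]
        keep = np.concatenate([[True], np.diff(st) > 0])  # strictness after rounding
        trains.append(
            SpikeTrain(neuron_id=f"n{i:03d}", spike_times=st[keep], subject_id=cfg.subject_id)
        )
        rows.append(
            {
                "neuron_id": f"n{i:03d}",
                "excited": bool(excited[i]),
                "baseline_hz": baseline[i],
                "early_amp_hz": early_amp[i],
                "late_amp_hz": late_amp[i],
            }
        )
    return trains, pd.DataFrame(rows), gain_matrix


def generate_session(config: SimulationConfig, seed: int) -> tuple[SessionBundle, GroundTruth]:
    """Compose schedule, behavior, and spikes into a validated bundle."""
    ss = np.random.SeedSequence(seed)
    s_sched, s_behav, s_spk = ss.spawn(3)
    schedule = generate_cue_schedule(config, s_sched)
    tracking, events_df, trial_truth, bouts_df = generate_behavior(schedule, config, s_behav)
    trains, neuron_truth, gain_matrix = generate_spike_trains(trial_truth, config, s_spk)
    manifest = SessionManifest(
        frame_rate_hz=config.frame_rate,
        duration_s=config.duration_s,
        arena_mm=tuple(config.arena_mm),
        lever_xy_mm=tuple(config.lever_xy_mm),
        receptacle_xy_mm=tuple(config.receptacle_xy_mm),
        subject_id=config.subject_id,
        session_id=config.session_id,
        infusion_time_s=config.infusion_time_s,
        infusion_condition=config.infusion_condition,
    )
    events_df = events_df.copy()
    events_df["time_s"] = np.round(events_df["time_s"], 6)
    bundle = SessionBundle(
        tracking=tracking,
        events=EventLog(events_df),
        neurons=trains,
        manifest=manifest,
    )
    truth = GroundTruth(
        trials=trial_truth,
        neurons=neuron_truth,
        bouts=bouts_df,
        itis=schedule.itis,
        config=config,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# lightweight epoch population (for attenuation recovery at desk scale)


def simulate_epoch_population(
    n_neurons: int,
    attenuation: float,
    seed,
    n_trials: int = 25,
    baseline_range=(5.0, 20.0),
    amp_range=(0.0, 120.0),
    window_ms=(40, 180),
):
    """Direct Q1/Q2 Z-score pairs from binned Poisson counts.

    Each neuron has a constant baseline and an evoked rate added over the
    response window; the evoked rate is multiplied by ``attenuation`` in Q2.
    Returns a DataFrame with z_q1 and z_q2 computed by the same Z statistic
    the epoch analysis uses.
    """
    from .spike_response import PeriCueCounts, response_zscore

    rng = np.random.default_rng(seed)
    edges = np.arange(-1000, 400 + 20, 20)
    n_bins = len(edges) - 1
    starts = edges[:-1]
    in_resp = (starts >= window_ms[0]) & (starts < window_ms[1])
    rows = []
    for i in range(n_neurons):
        b = rng.uniform(*baseline_range)
        amp = rng.uniform(*amp_range)
        zs = {}
        for epoch, factor in (("q1", 1.0), ("q2", attenuation)):
            lam = np.full(n_bins, b * 0.02)
            lam[in_resp] += amp * factor * 0.02
            counts = rng.poisson(lam, size=(n_trials, n_bins))
            pc = PeriCueCounts(
                neuron_id=f"n{i}", bin_edges_ms=edges, counts=counts,
                trial_ids=np.arange(n_trials),
            )
            zs[epoch] = response_zscore(pc, tuple(window_ms))
        rows.append({"neuron_id": f"n{i}", "z_q1": zs["q1"], "z_q2": zs["q2"]})
    return pd.DataFrame(rows)
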