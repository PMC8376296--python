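"""Locomotor index, mixture thresholds, bout segmentation, trial classes."""

import numpy as np
import pandas as pd
import pytest

from vpvigor import (
    EventLog,
    LocomotorThresholdModel,
    detect_bouts,
    classify_trials,
    fit_li_mixture,
    gaussian_intersection,
    locomotor_index,
)
from vpvigor.locomotion import LocomotorIndexSeries, MovementBout

from conftest import make_pose


# ---------------------------------------------------------------------------
# independent oracles

def li_oracle(positions, valid, hw):
    """Literal loop: sample SD of the 2*hw+1 displacements around each frame."""
    n = len(positions)
    out = np.full(n, np.nan)
    ok = np.zeros(n, bool)
    for t in range(n):
        lo_frame, hi_frame = t - hw - 1, t + hw
        if lo_frame < 0 or hi_frame >= n:
            continue
        if not all(valid[lo_frame : hi_frame + 1]):
            continue
        ds = []
        for a in range(t - hw, t + hw + 1):
            ds.append(float(np.hypot(*(positions[a] - positions[a - 1]))))
        m = sum(ds) / len(ds)
        out[t] = (sum((d - m) ** 2 for d in ds) / (len(ds) - 1)) ** 0.5
        ok[t] = True
    return out, ok


def bout_oracle(li_vals, valid, on_thr, off_thr, still_w=30, still_frac=0.7, run=4):
    """Frame-by-frame scanner implementing the stated onset/offset rules."""
    n = len(li_vals)
    above = [bool(valid[i]) and li_vals[i] > on_thr for i in range(n)]
    below = [bool(valid[i]) and li_vals[i] < off_thr for i in range(n)]
    bouts = []
    t = 0
    while t <= n - run:
        run_ok = all(above[t : t + run])
        window = below[max(0, t - still_w) : t]
        still_ok = sum(window) >= still_frac * still_w
        if run_ok and still_ok:
            off = next((u for u in range(t + 1, n) if below[u]), n - 1)
            bouts.append((t, off))
            t = off + 1
        else:
            t += 1
    return bouts


class FakeThresholds:
    def __init__(self, offset, onset):
        self.offset_threshold_ = offset
        self.onset_threshold_ = onset


# ---------------------------------------------------------------------------
# locomotor index

def test_li_zero_for_still_and_constant_velocity():
    still = make_pose(np.full(40, 5.0))
    li = locomotor_index(still)
    assert np.allclose(li.li[li.valid], 0.0)
    line = make_pose(np.arange(40) * 2.0)  # constant 2 mm/frame
    li2 = locomotor_index(line)
    assert np.allclose(li2.li[li2.valid], 0.0, atol=1e-12)


def test_li_matches_literal_sd_on_accelerating_example():
    x = np.array([0, 0, 0, 0, 0, 0, 1, 3, 6, 10, 15, 21], dtype=float)
    pose = make_pose(x)
    li = locomotor_index(pose)
    expect, ok = li_oracle(pose.position, pose.valid, 4)
    center = 6  # a frame with a full window on both sides
    assert ok[center]
    assert li.li[center] == pytest.approx(expect[center], abs=1e-12)
    assert np.array_equal(li.valid, ok)


def test_li_equals_brute_force_on_random_trajectories(rng):
    for _ in range(60):
        n = int(rng.integers(12, 50))
        pos = rng.normal(0, 20, (n, 2))
        valid = rng.random(n) > 0.08
        pos[~valid] = np.nan
        pose = make_pose(pos[:, 0], pos[:, 1], valid=valid)
        li = locomotor_index(pose)
        expect, ok = li_oracle(pose.position, valid, 4)
        assert np.array_equal(li.valid, ok)
        assert np.allclose(li.li[ok], expect[ok], atol=1e-12)


def test_li_short_series_all_invalid():
    li = locomotor_index(make_pose(np.arange(6.0)))
    assert not li.valid.any()


# ---------------------------------------------------------------------------
# gaussian intersection and mixture

def test_intersection_symmetric_case():
    x, flagged = gaussian_intersection((0.5, 0.0, 1.0), (0.5, 2.0, 1.0))
    assert not flagged
    assert x == pytest.approx(1.0, abs=1e-12)


def test_intersection_defining_property(rng):
    for _ in range(50):
        w1, w2 = rng.uniform(0.05, 0.95, 2)
        m1 = rng.uniform(-3, 0)
        m2 = m1 + rng.uniform(0.5, 5)
        s1, s2 = rng.uniform(0.2, 2.0, 2)
        x, flagged = gaussian_intersection((w1, m1, s1), (w2, m2, s2))
        if flagged:
            continue
        d1 = w1 / s1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
        d2 = w2 / s2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)
        assert d1 == pytest.approx(d2, abs=1e-9)


def test_intersection_dominance_fallback_matches_grid():
    x, flagged = gaussian_intersection((0.999, 0.0, 1.0), (0.001, 1.0, 1.0))
    assert flagged
    grid = np.linspace(0, 1, 4096)[1:-1]
    d1 = 0.999 * np.exp(-0.5 * grid**2)
    d2 = 0.001 * np.exp(-0.5 * (grid - 1) ** 2)
    assert x == pytest.approx(grid[np.argmin(np.abs(d1 - d2))], abs=1e-9)


def test_intersection_identical_components_error():
    with pytest.raises(ValueError):
        gaussian_intersection((0.5, 1.0, 1.0), (0.5, 1.0, 1.0))


def test_mixture_recovers_generating_parameters():
    rng = np.random.default_rng(77)
    weights, means, sds = [0.5, 0.3, 0.2], [0.5, 5.0, 20.0], [0.2, 1.5, 5.0]
    comp = rng.choice(3, 30_000, p=weights)
    sample = rng.normal(np.take(means, comp), np.take(sds, comp))
    model = fit_li_mixture(sample, seed=0)
    assert np.allclose(model.means_, means, rtol=0.05)
    assert model.offset_threshold_ < model.onset_threshold_
    assert means[0] < model.offset_threshold_ < means[1]
    assert means[1] < model.onset_threshold_ < means[2]


def test_mixture_degenerate_input_errors():
    with pytest.raises(ValueError):
        fit_li_mixture(np.full(5000, 3.0), seed=0)
    with pytest.raises(ValueError):
        fit_li_mixture(np.arange(100), seed=0)  # too few values


def test_mixture_components_sorted_and_thresholds_ordered_over_seeds():
    rng = np.random.default_rng(3)
    for seed in range(25):
        comp = rng.choice(3, 4000, p=[0.5, 0.3, 0.2])
        sample = rng.normal(np.take([0.8, 3.0, 9.0], comp), np.take([0.3, 1.0, 3.0], comp))
        model = LocomotorThresholdModel(n_init=3, random_state=seed).fit(sample)
        assert np.all(np.diff(model.means_) > 0)
        assert model.offset_threshold_ < model.onset_threshold_


# ---------------------------------------------------------------------------
# bout detection

def _series(values, fr=30.0):
    values = np.asarray(values, dtype=float)
    return LocomotorIndexSeries(values, np.isfinite(values), 4, fr)


def test_square_wave_single_bout():
    li = _series([0.1] * 60 + [30.0] * 20 + [0.1] * 20)
    bouts = detect_bouts(li, FakeThresholds(1.0, 10.0))
    assert len(bouts) == 1
    assert bouts[0].onset_frame == 60
    assert bouts[0].offset_frame == 80


def test_no_bout_when_below_onset():
    li = _series([0.5] * 200)
    assert detect_bouts(li, FakeThresholds(1.0, 10.0)) == []


def test_detect_bouts_matches_frame_scanner_on_random_walks(rng):
    thr = FakeThresholds(1.0, 3.0)
    for _ in range(120):
        n = int(rng.integers(80, 400))
        vals = np.abs(np.cumsum(rng.normal(0, 1.0, n)))
        vals[rng.random(n) < 0.03] = np.nan
        li = _series(vals)
        got = [(b.onset_frame, b.offset_frame) for b in detect_bouts(li, thr)]
        expect = bout_oracle(vals, np.isfinite(vals), 3.0, 1.0)
        assert got == expect


def test_bout_predicates_hold_when_rechecked(rng):
    thr = FakeThresholds(1.0, 3.0)
    vals = np.abs(np.cumsum(rng.normal(0, 1.0, 3000)))
    li = _series(vals)
    bouts = detect_bouts(li, thr)
    prev_off = -1
    for b in bouts:
        assert b.onset_frame > prev_off
        prev_off = b.offset_frame
        assert all(vals[b.onset_frame : b.onset_frame + 4] > 3.0)
        window = vals[max(0, b.onset_frame - 30) : b.onset_frame]
        assert np.sum(window < 1.0) >= 0.7 * 30


# ---------------------------------------------------------------------------
# trial classification

def _events(rows):
    return EventLog(pd.DataFrame(rows, columns=["time_s", "kind", "payload"]))


def test_cue_inside_bout_excluded():
    vals = [0.1] * 60 + [30.0] * 30 + [0.1] * 60
    li = _series(vals)
    thr = FakeThresholds(1.0, 10.0)
    bouts = detect_bouts(li, thr)
    ev = _events([(2.5, "DS_on", ""), (5.0, "DS_off", "")])  # frame 75, inside bout
    (rec,) = classify_trials(bouts, ev, li, thr)
    assert not rec.still_at_cue
    assert rec.excluded_reason == "moving_at_cue"
    assert np.isnan(rec.movement_start_time)


def test_responded_trial_latency_and_press_end():
    # cue at 100.0 s, movement bout onset 100.4 s (frame 3012), press 101.5 s
    n = 3200
    vals = np.full(n, 0.1)
    vals[3012:3100] = 30.0
    li = _series(vals)
    thr = FakeThresholds(1.0, 10.0)
    bouts = detect_bouts(li, thr)
    ev = _events(
        [(100.0, "DS_on", ""), (101.5, "active_press", ""), (101.5, "DS_off", "")]
    )
    (rec,) = classify_trials(bouts, ev, li, thr)
    assert rec.still_at_cue and rec.responded
    assert rec.movement_onset_latency == pytest.approx(0.4, abs=1 / 30)
    assert rec.end_rule == "press"
    assert rec.movement_end_time == pytest.approx(101.5)


def test_nonresponded_trial_ends_at_first_subthreshold_frame():
    n = 3400
    vals = np.full(n, 0.1)
    vals[3012:3200] = 30.0
    vals[3200:3230] = 5.0  # below onset, above offset: bout continues
    li = _series(vals)
    thr = FakeThresholds(1.0, 10.0)
    bouts = detect_bouts(li, thr)
    ev = _events([(100.0, "NS_on", ""), (110.0, "NS_off", "")])
    (rec,) = classify_trials(bouts, ev, li, thr)
    assert not rec.responded
    assert rec.end_rule == "li_offset"
    first_below = next(i for i in range(3013, n) if vals[i] < 1.0)
    assert rec.movement_end_time == pytest.approx(first_below / 30.0)


def test_movement_start_for_responded_trial_precedes_press():
    # first bout after the press must not be used as the movement start
    n = 4000
    vals = np.full(n, 0.1)
    vals[3300:3400] = 30.0  # bout well after the press at 101.5 s
    li = _series(vals)
    thr = FakeThresholds(1.0, 10.0)
    bouts = detect_bouts(li, thr)
    ev = _events(
        [(100.0, "DS_on", ""), (101.5, "active_press", ""), (101.5, "DS_off", "")]
    )
    (rec,) = classify_trials(bouts, ev, li, thr)
    assert rec.excluded_reason == "no_onset_detected"
    assert np.isnan(rec.movement_start_time)


# ---------------------------------------------------------------------------
# parameter recovery on synthetic sessions

def test_ground_truth_onsets_recovered_within_three_frames():
    """Initiations above the noise floor, after >=1 s of stillness, are
    found within +-3 frames in >=95% of cases."""
    from vpvigor import SimulationConfig, generate_session, head_pose

    hits = []
    for seed in (1, 2, 3, 4, 5):
        cfg = SimulationConfig(
            duration_s=2400.0,
            n_neurons=2,
            fidget_prob=0.15,
            fidget_step_mm=2.8,
            still_mean_s=8.0,
            latency_median_s=1.6,
            latency_sigma=0.25,
            approach_peak_speed_median=550.0,
            approach_peak_speed_sigma=0.12,
            approach_min_duration_s=0.6,
        )
        bundle, truth = generate_session(cfg, seed)
        pose = head_pose(bundle.tracking)
        li = locomotor_index(pose)
        thr = fit_li_mixture(li.li[li.valid], seed=seed)
        onsets = np.array([b.onset_time for b in detect_bouts(li, thr)])
        moves = truth.bouts
        resp = truth.trials[truth.trials.responded & ~truth.trials.moving_at_cue]
        for _, r in resp.iterrows():
            ms = r.movement_start
            prev = moves[moves.end_s < ms - 1e-9]
            still_gap = ms - (prev.end_s.max() if len(prev) else 0.0)
            if still_gap >= 1.2 and r.true_speed_mean >= 250.0:
                hits.append(np.abs(onsets - ms).min() <= 3 / 30 + 1e-9)
    assert len(hits) >= 50
    assert np.mean(hits) >= 0.95
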