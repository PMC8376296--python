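"""Locomotor-bout segmentation from the locomotor index.

The *locomotor index* (LI) at frame ``t`` is the sample SD of the
``2*half_window + 1`` frame-to-frame head displacement magnitudes
``d[t-hw] .. d[t+hw]`` (``d[k]`` = Euclidean distance between head positions
at frames ``k`` and ``k-1``).  It is near zero when the head is still or
gliding at constant speed, and large during irregular, accelerating
locomotion, which makes its session-wide distribution multimodal.

Movement onset/offset thresholds are derived by fitting a three-component
Gaussian mixture to that distribution: the *onset* threshold is the
equal-density intersection of the second and third components (sorted by
mean) and the *offset* threshold the intersection of the first and second.
A movement bout starts at the first frame of a run of supra-onset-threshold
frames preceded by stillness (a fraction of the previous second below the
offset threshold) and ends at the first later frame back below the offset
threshold.  Trials are then classified against the bout list: trials where
the animal was already moving at cue onset are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .io import EventLog
from .kinematics import PoseSeries

DEFAULT_HALF_WINDOW = 4
DEFAULT_STILLNESS_WINDOW = 30  # frames (1 s at 30 Hz)
DEFAULT_STILLNESS_FRACTION = 0.7
DEFAULT_RUN_LENGTH = 4


@dataclass
class LocomotorIndexSeries:
    li: np.ndarray  # mm; NaN where invalid
    valid: np.ndarray  # bool
    half_window: int
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.li)


@dataclass
class MovementBout:
    onset_frame: int
    offset_frame: int
    onset_time: float
    offset_time: float
    truncated: bool = False  # reached end of session without a sub-threshold frame


@dataclass
class TrialRecord:
    cue_type: str
    cue_onset_time: float
    cue_offset_time: float
    still_at_cue: bool
    responded: bool
    movement_onset_latency: float = np.nan
    movement_start_time: float = np.nan
    movement_end_time: float = np.nan
    end_rule: Optional[str] = None  # press | port_entry | li_offset
    excluded_reason: Optional[str] = None


def locomotor_index(pose: PoseSeries, half_window: int = DEFAULT_HALF_WINDOW) -> LocomotorIndexSeries:
    """Sliding-window SD of frame displacements (sample SD, n-1 denominator).

    Frame ``t`` is valid only when every position in ``t-hw-1 .. t+hw`` is a
    valid pose sample; short series yield an all-invalid result rather than
    an error.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    n = pose.n_frames
    li = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    m = 2 * half_window + 1
    if n < m + 1:
        return LocomotorIndexSeries(li, valid, half_window, pose.frame_rate)
    disp = np.hypot(*(pose.position[1:] - pose.position[:-1]).T)  # d[k] at index k-1
    disp_ok = pose.valid[1:] & pose.valid[:-1]
    # windows of m consecutive displacements
    sw = np.lib.stride_tricks.sliding_window_view(disp, m)
    sw_ok = np.lib.stride_tricks.sliding_window_view(disp_ok, m).all(axis=1)
    sd = np.std(sw, axis=1, ddof=1)
    centers = np.arange(half_window + 1, n - half_window)  # frame t for each window
    li[centers] = np.where(sw_ok, sd, np.nan)
    valid[centers] = sw_ok
    return LocomotorIndexSeries(li, valid, half_window, pose.frame_rate)


def gaussian_intersection(lo, hi, grid_points: int = 4096) -> tuple[float, bool]:
    """Equal-density point of two weighted normal components, within (lo.mean, hi.mean).

    ``lo``/``hi`` are (weight, mean, sd) with lo.mean < hi.mean.  Solves the
    quadratic in x for equal weighted densities and returns the root inside
    the open interval.  When no root lies there (one component dominates
    throughout), returns the argmin of the absolute density difference over a
    dense grid, flagged (second return value True).
    """
    w1, m1, s1 = map(float, lo)
    w2, m2, s2 = map(float, hi)
    if not m1 < m2:
        raise ValueError("lo.mean must be < hi.mean")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sds must be positive")
    if abs(m1 - m2) < 1e-15 and abs(s1 - s2) < 1e-15 and abs(w1 - w2) < 1e-15:
        raise ValueError("identical components have no unique intersection")
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (
        0.5 * m2**2 / s2**2
        - 0.5 * m1**2 / s1**2
        + np.log(w1 / s1)
        - np.log(w2 / s2)
    )
    roots: list[float] = []
    if abs(a) < 1e-18:
        if abs(b) > 1e-18:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    inside = [r for r in roots if m1 < r < m2]
    if inside:
        # with two admissible roots take the one where densities are largest
        def logdens(x):
            return np.log(w1 / s1) - 0.5 * ((x - m1) / s1) ** 2
        return float(max(inside, key=logdens)), False
    grid = np.linspace(m1, m2, grid_points)[1:-1]
    d1 = w1 / s1 * np.exp(-0.5 * ((grid - m1) / s1) ** 2)
    d2 = w2 / s2 * np.exp(-0.5 * ((grid - m2) / s2) ** 2)
    return float(grid[np.argmin(np.abs(d1 - d2))]), True


class LocomotorThresholdModel(BaseEstimator):
    """Three-Gaussian mixture of locomotor-index values with threshold extraction.

    sklearn-style estimator: ``fit(li_values)`` EM-fits the mixture (k-means++
    initialization, ``n_init`` restarts, deterministic for a given
    ``random_state``) on a random subsample of at most ``max_samples`` valid
    values, sorts components by mean, and derives

    * ``offset_threshold_`` : intersection of components 1 and 2,
    * ``onset_threshold_``  : intersection of components 2 and 3.

    Fitted attributes follow the trailing-underscore convention; ``predict``
    labels values by most probable component (after sorting).
    """

    def __init__(
        self,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        max_samples: int = 20_000,
        random_state: int | None = 0,
    ):
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.max_samples = max_samples
        self.random_state = random_state

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        values = values[np.isfinite(values)]
        if values.size < 1000:
            raise ValueError("need at least 1000 valid locomotor-index values")
        if np.std(values) == 0:
            raise ValueError("degenerate input: zero variance")
        rng = np.random.default_rng(self.random_state)
        if values.size > self.max_samples:
            values = rng.choice(values, self.max_samples, replace=False)
        gm = GaussianMixture(
            n_components=3,
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
            init_params="k-means++",
            random_state=self.random_state,
        ).fit(values[:, None])
        order = np.argsort(gm.means_.ravel())
        self.weights_ = gm.weights_[order]
        self.means_ = gm.means_.ravel()[order]
        self.sds_ = np.sqrt(gm.covariances_.ravel()[order])
        comp = list(zip(self.weights_, self.means_, self.sds_))
        self.offset_threshold_, off_flag = gaussian_intersection(comp[0], comp[1])
        self.onset_threshold_, on_flag = gaussian_intersection(comp[1], comp[2])
        self.fallback_flags_ = {"offset": off_flag, "onset": on_flag}
        self.log_likelihood_ = float(gm.lower_bound_ * values.size)
        self.n_iter_ = int(gm.n_iter_)
        self.n_samples_ = int(values.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "means_")
        x = np.asarray(X, dtype=float).ravel()[:, None]
        log_p = (
            np.log(self.weights_)
            - np.log(self.sds_)
            - 0.5 * ((x - self.means_) / self.sds_) ** 2
        )
        return np.argmax(log_p, axis=1)


def fit_li_mixture(li_values, seed: int = 0) -> LocomotorThresholdModel:
    """Functional wrapper: fit the 3-Gaussian LI mixture and thresholds."""
    return LocomotorThresholdModel(random_state=seed).fit(li_values)


def detect_bouts(
    li: LocomotorIndexSeries,
    thresholds,
    stillness_window: int = DEFAULT_STILLNESS_WINDOW,
    stillness_fraction: float = DEFAULT_STILLNESS_FRACTION,
    run_length: int = DEFAULT_RUN_LENGTH,
) -> list[MovementBout]:
    """Segment movement bouts from the locomotor index.

    Onset = first frame of >= ``run_length`` consecutive frames with
    ``li > onset_threshold`` such that at least ``stillness_fraction`` of the
    ``stillness_window`` frames before the onset frame have
    ``li < offset_threshold``.  The bout's offset is the first subsequent
    frame with ``li < offset_threshold``.  Invalid-LI frames fail both
    comparisons.  Bouts are disjoint; a bout reaching the end of the session
    is closed at the last frame and flagged truncated.
    """
    onset_thr = float(thresholds.onset_threshold_)
    offset_thr = float(thresholds.offset_threshold_)
    if not offset_thr < onset_thr:
        raise ValueError("offset threshold must be below onset threshold")
    x = li.li
    n = len(x)
    if n == 0:
        return []
    with np.errstate(invalid="ignore"):
        above = (x > onset_thr) & li.valid
        below = (x < offset_thr) & li.valid
    # run_ok[t]: frames t .. t+run_length-1 all above
    run_ok = np.zeros(n, dtype=bool)
    if n >= run_length:
        run_ok[: n - run_length + 1] = (
            np.lib.stride_tricks.sliding_window_view(above, run_length).all(axis=1)
        )
    csum = np.concatenate([[0], np.cumsum(below)])
    need = stillness_fraction * stillness_window
    fr = li.frame_rate
    bouts: list[MovementBout] = []
    t = 0
    below_idx = np.flatnonzero(below)
    while t <= n - run_length:
        lo = max(0, t - stillness_window)
        if run_ok[t] and (csum[t] - csum[lo]) >= need:
            j = np.searchsorted(below_idx, t + 1)
            if j < below_idx.size:
                off = int(below_idx[j])
                truncated = False
            else:
                off = n - 1
                truncated = True
            bouts.append(
                MovementBout(
                    onset_frame=t,
                    offset_frame=off,
                    onset_time=t / fr,
                    offset_time=off / fr,
                    truncated=truncated,
                )
            )
            t = off + 1
        else:
            t += 1
    return bouts


def classify_trials(
    bouts: list[MovementBout],
    events: EventLog,
    li: LocomotorIndexSeries,
    thresholds,
) -> list[TrialRecord]:
    """One record per cue presentation.

    ``still_at_cue`` is True when the cue-onset frame lies inside no bout;
    moving-at-cue trials carry ``excluded_reason='moving_at_cue'`` and no
    movement fields.  Movement start is the first bout onset after cue onset.
    For responded trials (active press before cue offset) movement ends at the
    first active press or receptacle entry after movement start; otherwise at
    the first frame with LI below the offset threshold after movement start.
    """
    offset_thr = float(thresholds.offset_threshold_)
    fr = li.frame_rate
    n = li.n_frames
    with np.errstate(invalid="ignore"):
        below = (li.li < offset_thr) & li.valid
    below_idx = np.flatnonzero(below)
    presses = np.sort(events.times("active_press"))
    entries = np.sort(events.times("port_entry"))
    onsets = np.array([b.onset_time for b in bouts])
    records: list[TrialRecord] = []
    for _, cue in events.cue_onsets().iterrows():
        t0 = float(cue["time_s"])
        t_off = float(cue["offset_s"]) if np.isfinite(cue["offset_s"]) else t0 + 10.0
        cue_frame = int(round(t0 * fr))
        inside = any(b.onset_frame <= cue_frame <= b.offset_frame for b in bouts)
        responded = bool(np.any((presses > t0) & (presses <= t_off + 1e-9)))
        rec = TrialRecord(
            cue_type=str(cue["cue_type"]),
            cue_onset_time=t0,
            cue_offset_time=t_off,
            still_at_cue=not inside,
            responded=responded,
        )
        if inside:
            rec.excluded_reason = "moving_at_cue"
            records.append(rec)
            continue
        if cue_frame >= n - 1:
            rec.excluded_reason = "incomplete"
            records.append(rec)
            continue
        later = np.flatnonzero(onsets > t0 + 1e-9)
        if responded:
            # the approach must begin before the press that ends the trial
            first_press = presses[presses > t0][0]
            later = later[onsets[later] <= first_press + 1e-9]
        if later.size:
            k = int(later[0])
            start = float(onsets[k])
            rec.movement_start_time = start
            rec.movement_onset_latency = start - t0
            if responded:
                cand = []
                p = presses[presses > start]
                e = entries[entries > start]
                if p.size:
                    cand.append(("press", float(p[0])))
                if e.size:
                    cand.append(("port_entry", float(e[0])))
                if cand:
                    rule, end = min(cand, key=lambda it: it[1])
                    rec.end_rule = rule
                    rec.movement_end_time = end
                else:
                    rec.excluded_reason = "incomplete"
            else:
                start_frame = bouts[k].onset_frame
                j = np.searchsorted(below_idx, start_frame + 1)
                if j < below_idx.size:
                    rec.end_rule = "li_offset"
                    rec.movement_end_time = float(below_idx[j] / fr)
                else:
                    rec.excluded_reason = "incomplete"
        else:
            rec.excluded_reason = "no_onset_detected"
        records.append(rec)
    return records


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """TrialRecord list as a tidy table (one row per cue)."""
    return pd.DataFrame([r.__dict__ for r in records])
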