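"""Pre/post-infusion epoch comparison of cue-evoked responses.

The infusion is represented purely as an epoch boundary.  For each neuron a
response Z-score (mean response-window rate vs the 1-s precue baseline, both
computed within-epoch) is obtained separately for the 45-min preinfusion
epoch Q1 and the 45-min postinfusion epoch Q2.  Across neurons, Q2 Z-scores
are regressed on Q1 Z-scores by ordinary least squares; a slope below one
with an intercept near zero indicates a multiplicative attenuation of the
evoked response.  t tests are reported for intercept = 0, slope = 0, and
slope = 1, all with ``n - 2`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import EventLog, SpikeTrain
from .spike_response import align_counts, response_zscore

EPOCH_LENGTH_S = 45 * 60.0
MIN_EPOCH_TRIALS = 10


@dataclass
class EpochPair:
    neuron_id: str
    window: str  # early | late
    z_q1: float
    z_q2: float
    n_trials_q1: int
    n_trials_q2: int


def epoch_response_zscores(
    neuron: SpikeTrain,
    events: EventLog,
    epoch: tuple[float, float],
    window_ms,
    min_trials: int = MIN_EPOCH_TRIALS,
) -> tuple[float, int]:
    """Response Z over the DS trials whose onset falls inside ``epoch``.

    Returns (z, n_trials); z is NaN when the epoch holds fewer than
    ``min_trials`` DS onsets or the baseline SD is zero.
    """
    lo, hi = epoch
    onsets = events.times("DS_on")
    sel = onsets[(onsets >= lo) & (onsets < hi)]
    if sel.size < min_trials:
        return np.nan, int(sel.size)
    counts = align_counts(neuron, sel, window_ms=(-1000, 400))
    return response_zscore(counts, tuple(window_ms)), int(sel.size)


def epoch_boundaries(infusion_time_s: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Q1 = [infusion - 45 min, infusion), Q2 = [infusion, infusion + 45 min)."""
    return (
        (infusion_time_s - EPOCH_LENGTH_S, infusion_time_s),
        (infusion_time_s, infusion_time_s + EPOCH_LENGTH_S),
    )


class EpochSlopeRegression(BaseEstimator):
    """OLS of postinfusion on preinfusion Z-scores across neurons.

    ``fit(z_q1, z_q2)`` estimates ``z_q2 = intercept + slope * z_q1`` and the
    three t tests (intercept vs 0, slope vs 0, slope vs 1) with residual
    degrees of freedom ``n - 2``.

    Fitted attributes: ``slope_``, ``slope_se_``, ``intercept_``,
    ``intercept_se_``, ``t_intercept0_``, ``p_intercept0_``, ``t_slope0_``,
    ``p_slope0_``, ``t_slope1_``, ``p_slope1_``, ``df_``, ``n_``.
    """

    def __init__(self, min_pairs: int = 5):
        self.min_pairs = min_pairs

    def fit(self, z_q1, z_q2=None):
        x = np.asarray(z_q1, dtype=float).ravel()
        y = np.asarray(z_q2, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = x.size
        if n < self.min_pairs:
            raise ValueError(f"need >= {self.min_pairs} complete pairs, got {n}")
        sxx = float(((x - x.mean()) ** 2).sum())
        if sxx == 0:
            raise ValueError("zero variance in preinfusion Z-scores")
        slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
        intercept = float(y.mean() - slope * x.mean())
        resid = y - intercept - slope * x
        df = n - 2
        s2 = float((resid**2).sum() / df) if df > 0 else 0.0
        if s2 <= 1e-20 * max(float(np.var(y)), 1e-30):
            s2 = 0.0
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))

        def ttest(est, null, se):
            if se == 0:
                t = np.inf if est != null else 0.0
                return t, 0.0 if est != null else 1.0
            t = (est - null) / se
            return float(t), float(2 * stats.t.sf(abs(t), df))

        self.n_ = n
        self.df_ = df
        self.slope_ = slope
        self.intercept_ = intercept
        self.slope_se_ = float(slope_se)
        self.intercept_se_ = float(intercept_se)
        self.t_intercept0_, self.p_intercept0_ = ttest(intercept, 0.0, intercept_se)
        self.t_slope0_, self.p_slope0_ = ttest(slope, 0.0, slope_se)
        self.t_slope1_, self.p_slope1_ = ttest(slope, 1.0, slope_se)
        self.se_degenerate_ = slope_se == 0
        return self

    def predict(self, z_q1):
        check_is_fitted(self, "slope_")
        return self.intercept_ + self.slope_ * np.asarray(z_q1, dtype=float)

    def summary_row(self, condition: str = "", window: str = "") -> dict:
        check_is_fitted(self, "slope_")
        return {
            "condition": condition,
            "window": window,
            "slope": self.slope_,
            "slope_se": self.slope_se_,
            "intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "p_int0": self.p_intercept0_,
            "p_slope0": self.p_slope0_,
            "p_slope1": self.p_slope1_,
            "n": self.n_,
        }


def paired_epoch_regression(pairs: list[EpochPair]) -> EpochSlopeRegression:
    """Fit the Q2-on-Q1 regression from a list of complete epoch pairs."""
    x = [p.z_q1 for p in pairs]
    y = [p.z_q2 for p in pairs]
    return EpochSlopeRegression().fit(x, y)


def build_epoch_pairs(
    neurons: list[SpikeTrain],
    events: EventLog,
    infusion_time_s: float,
    windows: dict[str, tuple[int, int]],
    min_trials: int = MIN_EPOCH_TRIALS,
) -> pd.DataFrame:
    """Per-neuron Q1/Q2 Z-scores for each response window.

    Neurons lacking a valid Z in either epoch are omitted (complete pairs
    only).
    """
    q1, q2 = epoch_boundaries(infusion_time_s)
    rows = []
    for neuron in neurons:
        for wname, wms in windows.items():
            z1, n1 = epoch_response_zscores(neuron, events, q1, wms, min_trials)
            z2, n2 = epoch_response_zscores(neuron, events, q2, wms, min_trials)
            if np.isfinite(z1) and np.isfinite(z2):
                rows.append(
                    {
                        "neuron_id": neuron.neuron_id,
                        "window": wname,
                        "z_q1": z1,
                        "z_q2": z2,
                        "n_q1": n1,
                        "n_q2": n2,
                    }
                )
    return pd.DataFrame(rows, columns=["neuron_id", "window", "z_q1", "z_q2", "n_q1", "n_q2"])
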