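"""Peri-cue spike counting, excitation detection, and Z-scored responses.

Spikes are counted in consecutive 20-ms bins aligned to cue (or movement)
onset.  A neuron is *cue-excited* when three or more consecutive bins in the
40-180 ms detection window exceed an upper criterion derived from the 1-s
precue baseline: baseline mean + z * baseline SD of the trial-averaged
baseline bin rates, with z = 3.2905 (the two-sided 99.9% normal point).  A
Poisson-exact criterion on the summed baseline count is available as an
alternative.  Response Z-scores use the same baseline statistics:
Z = (mean response-window rate - baseline mean) / baseline SD.

Analysis windows follow the two-phase shape of the evoked response: an early
peak at 40-180 ms and a late tail at 180-400 ms after cue onset (40-400 ms
overall).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .io import SpikeTrain

BIN_MS = 20
BASELINE_WINDOW_MS = (-1000, 0)
DETECT_WINDOW_MS = (40, 180)
EARLY_WINDOW_MS = (40, 180)
LATE_WINDOW_MS = (180, 400)
OVERALL_WINDOW_MS = (40, 400)
Z_CRITERION = 3.2905  # upper point of the two-sided 99.9% normal interval
MIN_TRIALS = 10


@dataclass
class PeriCueCounts:
    """Trial x bin spike counts around an alignment event (20-ms bins)."""

    neuron_id: str
    bin_edges_ms: np.ndarray  # len n_bins + 1, ms relative to alignment
    counts: np.ndarray  # (n_trials, n_bins) int
    trial_ids: np.ndarray
    alignment: str = "cue_onset"

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def bin_slice(self, window_ms) -> slice:
        lo, hi = window_ms
        edges = self.bin_edges_ms
        i0 = int(np.searchsorted(edges, lo))
        i1 = int(np.searchsorted(edges, hi))
        if edges[i0] != lo or edges[i1] != hi:
            raise ValueError(f"window {window_ms} not aligned to bin edges")
        return slice(i0, i1)

    def window_rate_hz(self, window_ms) -> float:
        """Trial-and-time-averaged firing rate (Hz) in the window."""
        sl = self.bin_slice(window_ms)
        width_s = (window_ms[1] - window_ms[0]) / 1000.0
        return float(self.counts[:, sl].sum(axis=1).mean() / width_s)


@dataclass
class ExcitationProfile:
    neuron_id: str
    baseline_mean_hz: float
    baseline_sd_hz: float
    ci_upper_hz: float
    excited: bool
    onset_bin_ms: Optional[float]  # start of first supra-criterion bin after onset
    rate_early_hz: float
    rate_late_hz: float
    rate_overall_hz: float
    z_early: float
    z_late: float
    degenerate: bool = False


def align_counts(
    train: SpikeTrain,
    align_times,
    window_ms=( -1000, 400 ),
    bin_ms: int = BIN_MS,
    trial_ids=None,
) -> PeriCueCounts:
    """Bin spikes into half-open 20-ms bins around each alignment time.

    A spike at a bin's left edge counts in that bin; at the right edge it
    falls in the next.  Empty ``align_times`` gives an empty count matrix.
    """
    lo, hi = window_ms
    if lo % bin_ms or hi % bin_ms:
        raise ValueError("window bounds must be multiples of bin_ms")
    align_times = np.asarray(align_times, dtype=float)
    edges_ms = np.arange(lo, hi + bin_ms, bin_ms)
    n_bins = len(edges_ms) - 1
    counts = np.zeros((align_times.size, n_bins), dtype=int)
    spikes = np.asarray(train.spike_times, dtype=float)
    eps = 1e-6  # ms; guards bin-edge assignment against float error
    for i, t in enumerate(align_times):
        a = np.searchsorted(spikes, t + (lo - eps) / 1000.0, side="left")
        b = np.searchsorted(spikes, t + (hi - eps) / 1000.0, side="left")
        if b > a:
            rel_ms = (spikes[a:b] - t) * 1000.0
            idx = np.floor((rel_ms - lo + eps) / bin_ms).astype(int)
            np.add.at(counts[i], np.clip(idx, 0, n_bins - 1), 1)
    if trial_ids is None:
        trial_ids = np.arange(align_times.size)
    return PeriCueCounts(
        neuron_id=train.neuron_id,
        bin_edges_ms=edges_ms,
        counts=counts,
        trial_ids=np.asarray(trial_ids),
    )


def _baseline_stats(counts: PeriCueCounts, baseline_window_ms) -> tuple[float, float, np.ndarray]:
    sl = counts.bin_slice(baseline_window_ms)
    bin_s = BIN_MS / 1000.0
    rates = counts.counts[:, sl].mean(axis=0) / bin_s  # trial-averaged rate per bin
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return mean, sd, rates


def detect_excitation(
    counts: PeriCueCounts,
    baseline_window_ms=BASELINE_WINDOW_MS,
    detect_window_ms=DETECT_WINDOW_MS,
    run: int = 3,
    criterion: str = "normal",
) -> ExcitationProfile:
    """Classify a neuron as cue-excited and summarize its evoked response.

    ``criterion='normal'``: upper bound = baseline mean + 3.2905 x SD of the
    50 trial-averaged baseline bin rates.  ``criterion='poisson'``: the
    99.95%-quantile of a Poisson null with the pooled baseline rate,
    expressed as a rate.  Excitation requires >= ``run`` consecutive
    supra-criterion bins inside the detection window; the reported onset is
    the first supra-criterion bin after time 0 regardless of run membership.
    """
    if counts.n_trials < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} trials, got {counts.n_trials}")
    base_mean, base_sd, _ = _baseline_stats(counts, baseline_window_ms)
    bin_s = BIN_MS / 1000.0
    degenerate = base_sd == 0.0
    if criterion == "normal":
        ci_upper = base_mean + Z_CRITERION * base_sd
    elif criterion == "poisson":
        # pooled baseline count over all trials and baseline bins
        sl = counts.bin_slice(baseline_window_ms)
        mu_count = counts.counts[:, sl].mean() * counts.n_trials  # per-bin pooled mean
        crit_count = stats.poisson.ppf(0.9995, mu_count)
        ci_upper = crit_count / counts.n_trials / bin_s
    else:
        raise ValueError("criterion must be 'normal' or 'poisson'")

    mean_rates = counts.counts.mean(axis=0) / bin_s  # trial-averaged rate per bin
    edges = counts.bin_edges_ms
    starts = edges[:-1]
    with np.errstate(invalid="ignore"):
        supra = mean_rates > ci_upper
    if degenerate:
        # zero-variance baseline: any nonzero post-cue bin counts as supra
        supra = mean_rates > base_mean

    det = counts.bin_slice(detect_window_ms)
    det_supra = supra[det]
    excited = False
    if det_supra.size >= run:
        runs = np.lib.stride_tricks.sliding_window_view(det_supra, run).all(axis=1)
        excited = bool(runs.any())

    post = starts >= 0
    onset: Optional[float] = None
    post_supra = np.flatnonzero(supra & post)
    if post_supra.size:
        onset = float(starts[post_supra[0]])

    rate_early = counts.window_rate_hz(EARLY_WINDOW_MS)
    rate_late = counts.window_rate_hz(LATE_WINDOW_MS)
    rate_overall = counts.window_rate_hz(OVERALL_WINDOW_MS)
    z_early = (rate_early - base_mean) / base_sd if base_sd > 0 else np.nan
    z_late = (rate_late - base_mean) / base_sd if base_sd > 0 else np.nan
    return ExcitationProfile(
        neuron_id=counts.neuron_id,
        baseline_mean_hz=base_mean,
        baseline_sd_hz=base_sd,
        ci_upper_hz=float(ci_upper),
        excited=excited,
        onset_bin_ms=onset,
        rate_early_hz=rate_early,
        rate_late_hz=rate_late,
        rate_overall_hz=rate_overall,
        z_early=float(z_early),
        z_late=float(z_late),
        degenerate=degenerate,
    )


def response_zscore(
    counts: PeriCueCounts,
    response_window_ms,
    baseline_window_ms=BASELINE_WINDOW_MS,
) -> float:
    """Z of the mean response-window rate against the 1-s precue baseline.

    NaN (undefined) when the baseline SD is zero.
    """
    base_mean, base_sd, _ = _baseline_stats(counts, baseline_window_ms)
    if base_sd == 0:
        return np.nan
    rate = counts.window_rate_hz(response_window_ms)
    return float((rate - base_mean) / base_sd)


def compare_cue_responses(ds_values, ns_values) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (DS vs NS responses across neurons).

    Returns (V, two-sided p); exact for n <= 25 nonzero differences, normal
    approximation with continuity correction above.  All-zero differences
    give V = 0, p = 1.
    """
    ds = np.asarray(ds_values, dtype=float)
    ns = np.asarray(ns_values, dtype=float)
    if ds.shape != ns.shape or ds.size < 5:
        raise ValueError("need paired vectors of equal length >= 5")
    diffs = ds - ns
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 0.0, 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        ds, ns, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    # scipy reports the smaller of V+/V-; convention here is V = rank sum of
    # positive differences
    ranks = stats.rankdata(np.abs(nz))
    v_plus = float(ranks[nz > 0].sum())
    return v_plus, float(res.pvalue)


def latency_quartile_split(latencies, n_quartiles: int = 4) -> np.ndarray:
    """Quartile labels (0-based) of cue-to-movement latencies.

    Utility for descriptive movement-onset-aligned comparisons restricted to
    trials with > 200 ms cue-to-movement separation (filter upstream).
    """
    lat = np.asarray(latencies, dtype=float)
    qs = np.nanquantile(lat, np.linspace(0, 1, n_quartiles + 1)[1:-1])
    return np.digitize(lat, qs)
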