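"""Per-neuron Poisson encoding models and population inference.

Each neuron's cue-evoked spike count ``Y`` in a response window is modeled
with a log-link Poisson regression on the selected movement and state
regressors::

    ln E[Y] = beta_0 + beta_1 x_1 + ... + beta_n x_n

Regressors enter unstandardized; cross-regressor comparability comes from
the *IDR Firing Difference* (IFD) transform

    IFD = (exp(beta * IDR) - 1) * 100%

where IDR is the interdecile range (90th - 10th percentile) of the
regressor over the neuron's retained trials.  The IFD is the model-predicted
percent change in firing across the central 80% of the regressor's range.

Population inference: per regressor and response window, a two-sided
one-sample t test of the neurons' IFDs against zero with Holm's step-down
adjustment across the regressor family of that window; cross-subject
consistency is checked with a one-way ANOVA of IFDs across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .spike_response import PeriCueCounts

MIN_EXTRA_ROWS = 10  # fitting requires >= n_regressors + 10 trials
MIN_RESPONSE_RATIO = 0.80  # sessions below this DS response ratio are excluded


@dataclass
class DesignMatrix:
    neuron_id: str
    y: np.ndarray  # spike counts per retained trial
    X: pd.DataFrame  # retained trial x regressor values (no intercept column)
    window_ms: tuple[int, int]
    trial_ids: np.ndarray
    dropped_trials: dict[str, int] = field(default_factory=dict)
    fittable: bool = True


def build_design(
    trials: pd.DataFrame,
    counts: PeriCueCounts,
    window_ms,
    regressors: list[str],
) -> DesignMatrix:
    """Assemble the per-neuron design: retained trials and window counts.

    Retains DS trials with a correct response, still at cue onset, and
    complete regressor values.  ``trials`` must carry one row per cue with
    columns ``cue_type``, ``responded``, ``still_at_cue``, ``trial_id`` and
    the regressor columns; ``counts.trial_ids`` links count rows to trials.
    """
    t = trials.copy()
    dropped = {
        "not_ds": int((t["cue_type"] != "DS").sum()),
    }
    t = t[t["cue_type"] == "DS"]
    dropped["moving_at_cue"] = int((~t["still_at_cue"].astype(bool)).sum())
    t = t[t["still_at_cue"].astype(bool)]
    dropped["no_response"] = int((~t["responded"].astype(bool)).sum())
    t = t[t["responded"].astype(bool)]
    complete = t[regressors].notna().all(axis=1)
    dropped["incomplete_features"] = int((~complete).sum())
    t = t[complete]

    id_to_row = {tid: i for i, tid in enumerate(counts.trial_ids)}
    keep = t["trial_id"].map(id_to_row).dropna().astype(int)
    t = t.loc[keep.index]
    sl = counts.bin_slice(tuple(window_ms))
    y = counts.counts[keep.to_numpy(), sl].sum(axis=1)
    X = t[regressors].astype(float).reset_index(drop=True)
    fittable = len(y) >= len(regressors) + MIN_EXTRA_ROWS
    return DesignMatrix(
        neuron_id=counts.neuron_id,
        y=np.asarray(y, dtype=float),
        X=X,
        window_ms=tuple(window_ms),
        trial_ids=t["trial_id"].to_numpy(),
        dropped_trials=dropped,
        fittable=fittable,
    )


def interdecile_range(values) -> float:
    """90th - 10th percentile, linear-interpolation percentile rule."""
    v = np.asarray(values, dtype=float)
    p10, p90 = np.percentile(v, [10, 90])
    return float(p90 - p10)


def idr_firing_difference(beta: float, regressor_values) -> tuple[float, float]:
    """(IFD percent, IDR) for one coefficient.

    IFD = (exp(beta * IDR) - 1) * 100; a constant regressor gives IDR = 0 and
    IFD = 0 (flag upstream).
    """
    idr = interdecile_range(regressor_values)
    return float((np.exp(beta * idr) - 1.0) * 100.0), idr


class PoissonVigorGLM(BaseEstimator, RegressorMixin):
    """Log-link Poisson regression with the IDR Firing Difference transform.

    sklearn-style estimator over one neuron's design: ``fit(X, y)`` runs
    maximum-likelihood Poisson regression (intercept included) and converts
    each coefficient to its IFD using the regressor's interdecile range over
    the fitted trials.

    Fitted attributes: ``intercept_``, ``coef_``, ``se_``, ``pvalues_``
    (Wald), ``idr_``, ``ifd_percent_``, ``converged_``, ``regressors_``.
    """

    def __init__(self, max_iter: int = 200):
        self.max_iter = max_iter

    def fit(self, X, y):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("y must be nonnegative integer counts")
        exog = sm.add_constant(frame.to_numpy(dtype=float), has_constant="add")
        model = sm.GLM(y, exog, family=sm.families.Poisson())
        res = model.fit(maxiter=self.max_iter)
        self.converged_ = bool(res.converged) and np.all(np.isfinite(res.bse))
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.se_ = np.asarray(res.bse[1:], dtype=float)
        self.pvalues_ = np.asarray(res.pvalues[1:], dtype=float)
        self.regressors_ = [str(c) for c in frame.columns]
        self.idr_ = np.array(
            [interdecile_range(frame[c]) for c in frame.columns], dtype=float
        )
        self.ifd_percent_ = (np.exp(self.coef_ * self.idr_) - 1.0) * 100.0
        self._result = res
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        arr = np.asarray(X, dtype=float)
        return np.exp(self.intercept_ + arr @ self.coef_)

    def effects_frame(self, neuron_id: str = "", window: str = "") -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        return pd.DataFrame(
            {
                "neuron_id": neuron_id,
                "window": window,
                "regressor": self.regressors_,
                "beta": self.coef_,
                "se": self.se_,
                "p": self.pvalues_,
                "idr": self.idr_,
                "ifd_percent": self.ifd_percent_,
                "converged": self.converged_,
            }
        )


def fit_poisson_glm(design: DesignMatrix) -> PoissonVigorGLM:
    """Fit the per-neuron model; raises on an unfittable design."""
    if not design.fittable:
        raise ValueError(
            f"neuron {design.neuron_id}: {len(design.y)} trials is fewer than "
            f"{design.X.shape[1]} regressors + {MIN_EXTRA_ROWS}"
        )
    return PoissonVigorGLM().fit(design.X, design.y)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="holm")[1]


def population_ifd_tests(ifd: pd.DataFrame, window: str = "", alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t tests of mean IFD vs 0, Holm-adjusted across regressors.

    ``ifd`` is a neuron x regressor matrix of IFD percentages; the Holm
    family is the regressor set of this window.  Regressors with zero
    variance get NaN statistics (undefined t).
    """
    if ifd.shape[0] < 3:
        raise ValueError("need >= 3 neurons")
    rows = []
    for name in ifd.columns:
        v = ifd[name].dropna().to_numpy(dtype=float)
        n = v.size
        sd = v.std(ddof=1) if n > 1 else 0.0
        if n >= 3 and sd == 0 and v.mean() == 0:
            rows.append((name, 0.0, 0.0, n - 1, 0.0, 1.0))
            continue
        if n < 3 or sd == 0:
            rows.append((name, np.nan, np.nan, n - 1, np.nan, np.nan))
            continue
        t, p = stats.ttest_1samp(v, 0.0)
        rows.append((name, v.mean(), sd / np.sqrt(n), n - 1, float(t), float(p)))
    out = pd.DataFrame(
        rows, columns=["regressor", "mean_ifd", "se", "df", "t", "p_raw"]
    )
    out["window"] = window
    mask = out["p_raw"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = holm_adjust(out.loc[mask, "p_raw"])
    out["p_holm"] = adj
    out["significant"] = out["p_holm"] < alpha
    out["n_neurons"] = ifd.shape[0]
    return out


def cross_subject_anova(ifd_values, subject_labels) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA of per-neuron IFDs across subjects.

    Subjects with a single neuron are excluded (with fewer than 2 remaining
    groups the test is undefined).  Returns (F, (df_between, df_within), p).
    """
    v = np.asarray(ifd_values, dtype=float)
    labels = np.asarray(subject_labels)
    groups = []
    for lab in pd.unique(labels):
        g = v[labels == lab]
        g = g[np.isfinite(g)]
        if g.size >= 2:
            groups.append(g)
    if len(groups) < 2:
        raise ValueError("need >= 2 subjects with >= 2 neurons each")
    f, p = stats.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    return float(f), (df_between, df_within), float(p)
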