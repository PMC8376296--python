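"""Regressor selection for the neural encoding model.

The candidate movement variables are highly redundant, so before fitting
per-neuron GLMs the variable set is reduced in four steps:

1. *Multicollinearity filter*: each variable's squared multiple correlation
   (SMC; the R^2 of regressing it on all the others) is computed, and
   variables are iteratively dropped (highest SMC first) while any SMC
   exceeds a tolerance (default 0.8).
2. *Factor count*: eigenvalues of the correlation matrix; the number of
   retained factors is the count of eigenvalues above 1 (Kaiser's
   criterion).
3. *Factor analysis* with varimax rotation, factors ordered by explained
   variance.
4. *Representative selection*: each variable's *rep score* is its highest
   factor loading minus the signed sum of its loadings on the other factors.
   Per factor, the assigned variable with |loading| >= ``strong`` and the
   highest rep score is chosen as the factor's representative; variables
   whose largest |loading| is below ``independent`` enter the model as
   standalone regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FactorAnalysis
from sklearn.utils.validation import check_is_fitted

SMC_TOLERANCE = 0.8
STRONG_LOADING = 0.6
INDEPENDENT_LOADING = 0.4


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr, columns=[f"v{i}" for i in range(arr.shape[1])])


def smc_scores(data) -> pd.Series:
    """Squared multiple correlation of each variable on all the others.

    Computed on complete rows.  Constant columns get NaN (undefined).
    """
    frame = _as_frame(data).dropna()
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if frame.shape[0] <= frame.shape[1]:
        raise ValueError("need more complete rows than variables")
    out = pd.Series(index=frame.columns, dtype=float)
    y_all = frame.to_numpy(dtype=float)
    const = y_all.std(axis=0) == 0
    for j, name in enumerate(frame.columns):
        if const[j]:
            out[name] = np.nan
            continue
        y = y_all[:, j]
        X = np.column_stack([np.ones(len(y)), np.delete(y_all, j, axis=1)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        out[name] = 1.0 - float((resid**2).sum()) / ss_tot
    return out


def filter_multicollinear(data, tolerance: float = SMC_TOLERANCE) -> tuple[list[str], list[str]]:
    """Iteratively drop the highest-SMC variable while any SMC > tolerance.

    Ties break by variable-name order.  Returns (retained, dropped).
    """
    frame = _as_frame(data)
    dropped: list[str] = []
    while frame.shape[1] >= 2:
        smc = smc_scores(frame)
        over = smc[smc > tolerance]
        if over.empty:
            break
        worst = sorted(over.index[over == over.max()])[0]
        dropped.append(worst)
        frame = frame.drop(columns=[worst])
    return list(frame.columns), dropped


def pca_factor_count(data) -> tuple[np.ndarray, int]:
    """Eigenvalues of the correlation matrix (descending) and Kaiser count (> 1)."""
    frame = _as_frame(data).dropna()
    if frame.shape[1] < 3:
        raise ValueError("need at least 3 variables")
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    return eig, int(np.sum(eig > 1.0))


def rep_scores(loadings) -> pd.Series:
    """Per-variable rep score: highest loading minus signed sum of the rest.

    'Highest' is the loading of largest magnitude (sign retained).
    """
    frame = _as_frame(loadings)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 factors")
    arr = frame.to_numpy(dtype=float)
    top = np.argmax(np.abs(arr), axis=1)
    highest = arr[np.arange(len(arr)), top]
    rest = arr.sum(axis=1) - highest
    return pd.Series(highest - rest, index=frame.index)


def _varimax_loadings(frame: pd.DataFrame, n_factors: int, rotation: str | None):
    """Standardized-data FA loadings, factors ordered by explained variance."""
    X = frame.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    fa = FactorAnalysis(
        n_components=n_factors, rotation=rotation, max_iter=5000, random_state=0
    ).fit(Xs)
    load = fa.components_.T  # variables x factors
    order = np.argsort(-(load**2).sum(axis=0), kind="stable")
    load = load[:, order]
    # sign convention: largest-|loading| entry of each factor positive
    for j in range(load.shape[1]):
        k = np.argmax(np.abs(load[:, j]))
        if load[k, j] < 0:
            load[:, j] = -load[:, j]
    cols = [f"factor{j + 1}" for j in range(load.shape[1])]
    return pd.DataFrame(load, index=frame.columns, columns=cols), fa


@dataclass
class SelectionReport:
    smc: pd.Series
    dropped_multicollinear: list[str]
    eigenvalues: np.ndarray
    n_factors: int
    loadings: pd.DataFrame
    rep_scores: pd.Series
    factor_assignment: pd.Series
    representatives: dict[str, str]
    independents: list[str]
    selected: list[str]
    manual_overrides: dict[str, str] = field(default_factory=dict)


class FactorRegressorSelector(BaseEstimator, TransformerMixin):
    """Select low-redundancy representative regressors from a variable table.

    sklearn-style transformer: ``fit(X)`` runs the SMC filter, Kaiser factor
    count, varimax factor analysis, and rep-score selection on a trial x
    variable DataFrame; ``transform(X)`` returns the selected columns.

    Parameters
    ----------
    smc_tolerance : drop variables while any SMC exceeds this (default 0.8).
    strong : minimum |loading| for a variable to represent its factor.
    independent : variables whose largest |loading| is below this enter the
        selection as standalone (factor-independent) regressors.
    rotation : 'varimax' (default) or None for the unrotated solution.
    n_factors : fixed factor count, or None to use Kaiser's criterion.
    manual_overrides : {factor_name: variable_name} forcing a representative.

    Fitted attributes: ``smc_``, ``dropped_``, ``eigenvalues_``,
    ``n_factors_``, ``loadings_``, ``rep_scores_``, ``assignment_``,
    ``representatives_``, ``independents_``, ``selected_``, ``report_``.
    """

    def __init__(
        self,
        smc_tolerance: float = SMC_TOLERANCE,
        strong: float = STRONG_LOADING,
        independent: float = INDEPENDENT_LOADING,
        rotation: str | None = "varimax",
        n_factors: int | None = None,
        manual_overrides: dict | None = None,
    ):
        self.smc_tolerance = smc_tolerance
        self.strong = strong
        self.independent = independent
        self.rotation = rotation
        self.n_factors = n_factors
        self.manual_overrides = manual_overrides

    def fit(self, X, y=None):
        frame = _as_frame(X).dropna()
        self.smc_ = smc_scores(frame)
        retained, self.dropped_ = filter_multicollinear(frame, self.smc_tolerance)
        frame = frame[retained]
        self.eigenvalues_, kaiser = pca_factor_count(frame)
        self.n_factors_ = int(self.n_factors) if self.n_factors else max(kaiser, 1)
        if self.n_factors_ >= frame.shape[1]:
            raise ValueError("n_factors must be smaller than the number of variables")
        self.loadings_, self._fa = _varimax_loadings(frame, self.n_factors_, self.rotation)
        self.rep_scores_ = rep_scores(self.loadings_)
        sel = select_regressors(
            self.loadings_,
            self.rep_scores_,
            strong=self.strong,
            independent=self.independent,
            manual_overrides=self.manual_overrides,
        )
        self.representatives_, self.independents_, self.selected_, self.assignment_ = sel
        self.report_ = SelectionReport(
            smc=self.smc_,
            dropped_multicollinear=self.dropped_,
            eigenvalues=self.eigenvalues_,
            n_factors=self.n_factors_,
            loadings=self.loadings_,
            rep_scores=self.rep_scores_,
            factor_assignment=self.assignment_,
            representatives=self.representatives_,
            independents=self.independents_,
            selected=self.selected_,
            manual_overrides=dict(self.manual_overrides or {}),
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_")
        return _as_frame(X)[self.selected_]


def select_regressors(
    loadings,
    rep=None,
    strong: float = STRONG_LOADING,
    independent: float = INDEPENDENT_LOADING,
    manual_overrides: dict | None = None,
):
    """Pick per-factor representatives and factor-independent variables.

    Per factor: among variables assigned to it (largest-|loading| factor)
    with |loading| >= ``strong``, the one with the highest rep score wins
    (ties by higher |loading|, then name); a factor with no qualifying
    variable is skipped.  Variables whose max |loading| < ``independent``
    are returned as independents.  ``manual_overrides`` maps factor name to
    a forced representative.

    Returns (representatives, independents, selected, assignment).
    """
    frame = _as_frame(loadings)
    rep = rep_scores(frame) if rep is None else pd.Series(rep, index=frame.index)
    arr = frame.to_numpy(dtype=float)
    assignment = pd.Series(
        [frame.columns[k] for k in np.argmax(np.abs(arr), axis=1)], index=frame.index
    )
    max_abs = pd.Series(np.max(np.abs(arr), axis=1), index=frame.index)
    overrides = dict(manual_overrides or {})
    representatives: dict[str, str] = {}
    for factor in frame.columns:
        if factor in overrides:
            representatives[factor] = overrides[factor]
            continue
        members = [
            v
            for v in frame.index
            if assignment[v] == factor and abs(frame.loc[v, factor]) >= strong
        ]
        if not members:
            continue
        members.sort(key=lambda v: (-rep[v], -abs(frame.loc[v, factor]), str(v)))
        representatives[factor] = members[0]
    independents = [v for v in frame.index if max_abs[v] < independent]
    selected = list(dict.fromkeys(list(representatives.values()) + independents))
    if not selected:
        raise ValueError("selection is empty: no representatives and no independents")
    return representatives, independents, selected, assignment
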