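"""Bidirectional stepwise AIC selection of linear predictors.

Mirrors the conventional R workflow of handing a full linear model to
stepAIC with both directions enabled: starting from the full model, every
single-term deletion and addition is scored at each step and the move with
the largest AIC decrease is applied until no move helps.  Fits are ordinary
least squares (statsmodels OLS); AIC counts the error variance, i.e.
``AIC = -2 loglik + 2 (n_coef + 1)`` — the extra constant is shared by every
candidate model so either counting convention selects identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LinearFit",
    "fit_linear",
    "significance_bands",
    "StepwiseAIC",
    "stepwise_select",
]

# Threshold order matters: first matching band wins.  The "p = 0" band is
# interpreted as p below double precision resolution.
SIGNIFICANCE_BANDS = (
    (1e-16, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


@dataclass
class LinearFit:
    """Gaussian OLS fit summary used by the stepwise search."""

    terms: tuple[str, ...]
    coef: pd.Series
    pvalues: pd.Series
    resid_var: float
    loglik: float
    aic: float
    n: int
    dropped_collinear: tuple[str, ...] = field(default=())


def _drop_collinear(x: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right removal of columns that are linear combinations of
    the preceding ones (e.g. vegetative + non-vegetative cover ~ 100)."""
    keep: list[str] = []
    dropped: list[str] = []
    arr = np.column_stack([np.ones(len(x))] + [x[c].to_numpy(float) for c in x.columns])
    cur = arr[:, :1]
    for k, c in enumerate(x.columns, start=1):
        trial = np.column_stack([cur, arr[:, k]])
        if np.linalg.matrix_rank(trial) > cur.shape[1]:
            keep.append(c)
            cur = trial
        else:
            dropped.append(c)
    return x[keep], dropped


def fit_linear(y, X: pd.DataFrame) -> LinearFit:
    """OLS of ``y`` on the columns of ``X`` plus an intercept.

    Collinear columns are dropped (reported on the result) before fitting;
    ``AIC = -2 loglik + 2 k`` with k = number of coefficients + 1 for the
    error variance.  Raises when there are not more observations than
    parameters.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = pd.DataFrame(X)
    if len(X) != y.size:
        raise ValueError("y and X length mismatch")
    xr, dropped = _drop_collinear(X)
    if dropped:
        warnings.warn(
            f"dropped collinear candidate column(s): {dropped}", UserWarning,
            stacklevel=2,
        )
    k = xr.shape[1] + 2  # coefficients incl. intercept, plus the variance
    if y.size <= k - 1:
        raise ValueError(f"need n > {k - 1} observations for {xr.shape[1]} terms")
    design = sm.add_constant(xr.to_numpy(float)) if xr.shape[1] else np.ones((y.size, 1))
    res = sm.OLS(y, design).fit()
    names = ["intercept", *xr.columns]
    return LinearFit(
        terms=tuple(xr.columns),
        coef=pd.Series(res.params, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        resid_var=float(res.ssr / y.size),  # ML variance, matches the loglik
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * k),
        n=y.size,
        dropped_collinear=tuple(dropped),
    )


def significance_bands(pvalues) -> "pd.Series":
    """Star labels for p-values: '****' below double precision (printed as
    p = 0), '***' below 0.001, '**' below 0.01, '*' below 0.05, else ''."""
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series("", index=p.index, dtype=object)
    for thr, label in SIGNIFICANCE_BANDS:
        out[(p < thr) & (out == "")] = label
    return out


class StepwiseAIC(RegressorMixin, BaseEstimator):
    """Bidirectional stepwise-AIC linear model selection.

    Parameters
    ----------
    direction : {"both", "forward", "backward"}
        "both" starts from the full model and considers additions and
        deletions each step; "forward" starts from the intercept and only
        adds; "backward" starts full and only deletes.
    start : {"full", "intercept"} or None
        Override the conventional start point of the chosen direction.

    Ties between equally improving moves are broken toward deletion first,
    then alphabetically by term name, so the search is deterministic.

    Attributes
    ----------
    selected_ : tuple of retained predictor names
    fit_ : LinearFit of the selected model
    results_ : DataFrame (term, coef, sign, p, band) for the selected model
    path_ : list of (action, term, aic) visited moves
    adj_r2_ : adjusted R² of the selected model
    """

    def __init__(self, direction: str = "both", start: str | None = None):
        self.direction = direction
        self.start = start

    def fit(self, X: pd.DataFrame, y):
        if self.direction not in ("both", "forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float).ravel())
        if X.shape[1] < 1:
            raise ValueError("need at least one candidate predictor")
        complete = X.notna().all(axis=1) & y.notna()
        self.n_dropped_rows_ = int((~complete).sum())
        if self.n_dropped_rows_:
            warnings.warn(
                f"dropped {self.n_dropped_rows_} incomplete row(s) before "
                "selection", UserWarning, stacklevel=2,
            )
        X, y = X.loc[complete].reset_index(drop=True), y[complete.to_numpy()].reset_index(drop=True)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            full = fit_linear(y, X)
        candidates = list(full.terms)  # largest full-rank subset
        if full.dropped_collinear:
            warnings.warn(
                "rank-deficient full model; starting from the largest "
                f"full-rank subset (dropped {list(full.dropped_collinear)})",
                UserWarning, stacklevel=2,
            )

        start = self.start or ("intercept" if self.direction == "forward" else "full")
        current = tuple(candidates) if start == "full" else ()
        cache: dict[tuple, LinearFit] = {}

        def fitted(terms: tuple) -> LinearFit:
            if terms not in cache:
                cache[terms] = fit_linear(y, X[list(terms)])
            return cache[terms]

        self.path_ = [("start", None, fitted(current).aic)]
        allow_del = self.direction in ("both", "backward")
        allow_add = self.direction in ("both", "forward")
        while True:
            best_aic = fitted(current).aic
            best_move = None
            moves = []
            if allow_del:
                moves += [("del", t) for t in sorted(current)]
            if allow_add:
                moves += [("add", t) for t in sorted(set(candidates) - set(current))]
            for action, term in moves:
                trial = (
                    tuple(t for t in current if t != term)
                    if action == "del"
                    else tuple([*current, term])
                )
                trial = tuple(t for t in candidates if t in trial)  # stable order
                aic = fitted(trial).aic
                if aic < best_aic - 1e-10:
                    best_aic, best_move = aic, (action, term, trial)
            if best_move is None:
                break
            action, term, current = best_move
            self.path_.append((action, term, best_aic))

        self.selected_ = current
        self.fit_ = fitted(current)
        self.aic_ = self.fit_.aic
        coef = self.fit_.coef.drop("intercept")
        pv = self.fit_.pvalues.drop("intercept")
        self.results_ = pd.DataFrame(
            {
                "coef": coef,
                "sign": np.where(coef >= 0, "+", "-"),
                "p": pv,
                "band": significance_bands(pv),
            }
        )
        self.results_.index.name = "term"
        n, k = self.fit_.n, len(self.selected_)
        ybar = y.mean()
        resid = y - self._predict_frame(X)
        r2 = 1.0 - float((resid**2).sum()) / float(((y - ybar) ** 2).sum())
        self.adj_r2_ = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_frame(self, X: pd.DataFrame) -> pd.Series:
        coef = self.fit_.coef
        out = pd.Series(coef["intercept"], index=X.index, dtype=float)
        for t in self.selected_:
            out += coef[t] * X[t].astype(float)
        return out

    def predict(self, X):
        check_is_fitted(self, "fit_")
        return self._predict_frame(pd.DataFrame(X)).to_numpy()


def stepwise_select(y, candidates: pd.DataFrame, direction: str = "both") -> StepwiseAIC:
    """Functional wrapper: fit a :class:`StepwiseAIC` and return it."""
    return StepwiseAIC(direction=direction).fit(candidates, y)
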