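"""Autocorrelation removal (prewhitening) before cross-correlation.

Cross-correlations between autocorrelated series have unreliable p-values,
so every series entering the association step is first reduced to model
residuals: continuous series via an exhaustive ARIMA grid (p <= 2, q <= 2,
d in {0, 1}, minimum BIC), binary-dominant series (>= 75% zeros) via a
Markov serial-dependence logistic regression of y_t on its previous one or
two values (minimum AIC).  If the residuals end up *more* autocorrelated at
lag 1 than the raw series, the model is discarded and the raw series is
used (``kind='passthrough'``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.tsa.arima.model import ARIMA


@dataclass
class DetrendModel:
    """Fitted detrending model and its residual series."""

    kind: str  # 'arima', 'binary-logistic', or 'passthrough'
    order: tuple  # (p, d, q) for ARIMA; (order,) for logistic
    criterion_value: float  # BIC (ARIMA) or AIC (logistic); nan for passthrough
    residuals: pd.Series


def _as_series(x) -> pd.Series:
    s = pd.Series(x) if not isinstance(x, pd.Series) else x
    return s.dropna().astype(float)


def lag1_autocorrelation(x) -> float:
    """Sample lag-1 autocorrelation (0 for degenerate series)."""
    v = np.asarray(x, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3 or np.ptp(v) == 0:
        return 0.0
    a, b = v[:-1], v[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def is_binary_dominant(series) -> bool:
    """True when at least 75% of observed values are exactly zero."""
    s = _as_series(series)
    if s.size == 0:
        raise ValueError("empty series")
    return bool((s == 0).mean() >= 0.75)


class ArimaDetrender(BaseEstimator, TransformerMixin):
    """Best-BIC ARIMA over the (p, d, q) grid; ``transform`` returns residuals.

    Attributes (after ``fit``): ``order_``, ``bic_``, ``result_``,
    ``residuals_``.  For d=1 models the first residual (an artifact of the
    diffuse prior) is dropped.
    """

    def __init__(self, max_p: int = 2, max_q: int = 2, max_d: int = 1):
        self.max_p = max_p
        self.max_q = max_q
        self.max_d = max_d

    def fit(self, X, y=None):
        s = _as_series(X)
        if s.size < 30:
            raise ValueError("series too short for ARIMA detrending (need >= 30)")
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for d in range(self.max_d + 1):
                for p in range(self.max_p + 1):
                    for q in range(self.max_q + 1):
                        try:
                            # concentrating the scale halves the fit time and
                            # leaves BIC unchanged; the parameter-free
                            # (0, d>0, 0) model needs the plain path
                            cs = not (p == 0 and q == 0 and d > 0)
                            res = ARIMA(
                                s.to_numpy(),
                                order=(p, d, q),
                                trend="c" if d == 0 else "n",
                                concentrate_scale=cs,
                            ).fit()
                        except Exception:
                            continue
                        if np.isfinite(res.bic) and (best is None or res.bic < best[0]):
                            best = (float(res.bic), (p, d, q), res)
        if best is None:
            self.order_ = None
            self.bic_ = np.nan
            self.residuals_ = s - s.mean()
            warnings.warn("no ARIMA fit converged; passthrough residuals", stacklevel=2)
            return self
        self.bic_, self.order_, self.result_ = best
        d = self.order_[1]
        self.residuals_ = pd.Series(self.result_.resid[d:], index=s.index[d:])
        return self

    def transform(self, X=None):
        return self.residuals_


def fit_arima_residuals(series) -> DetrendModel:
    """Exhaustive-grid ARIMA detrending of a continuous series."""
    est = ArimaDetrender().fit(series)
    if est.order_ is None:
        return DetrendModel("passthrough", (), np.nan, est.residuals_)
    return DetrendModel("arima", est.order_, est.bic_, est.residuals_)


def _logistic_nll(beta, X, y, ridge):
    z = X @ beta
    # log(1 + e^z) computed stably
    nll = np.sum(np.logaddexp(0.0, z) - y * z)
    return nll + ridge * np.dot(beta, beta)


def _fit_logistic(X, y, ridge=0.0):
    beta0 = np.zeros(X.shape[1])
    res = minimize(_logistic_nll, beta0, args=(X, y, ridge), method="BFGS")
    beta = res.x
    nll = _logistic_nll(beta, X, y, 0.0)
    return beta, nll


class BinaryLogisticDetrender(BaseEstimator, TransformerMixin):
    """Serial-dependence logistic model for binary-dominant series.

    Fits y_t ~ intercept + y_{t-1} (order 1) and + y_{t-2} (order 2) by
    maximum likelihood, keeps the lower-AIC order, and returns residuals
    ``y_t - fitted probability``.  Perfect separation falls back to a small
    ridge penalty with a warning.
    """

    def __init__(self, orders=(1, 2)):
        self.orders = orders

    def fit(self, X, y=None):
        s = _as_series(X)
        vals = s.to_numpy()
        if np.ptp(vals) == 0:
            raise ValueError("constant series; both values must be present")
        best = None
        for order in self.orders:
            yy = vals[order:]
            design = np.column_stack(
                [np.ones(vals.size - order)]
                + [vals[order - k : vals.size - k] for k in range(1, order + 1)]
            )
            beta, nll = _fit_logistic(design, yy)
            if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 30:
                warnings.warn(
                    "possible separation in serial logistic fit; using ridge",
                    stacklevel=2,
                )
                beta, nll = _fit_logistic(design, yy, ridge=1e-3)
            aic = 2.0 * nll + 2.0 * len(beta)
            if best is None or aic < best[0]:
                prob = 1.0 / (1.0 + np.exp(-(design @ beta)))
                resid = pd.Series(yy - prob, index=s.index[order:])
                best = (float(aic), order, beta, resid)
        self.aic_, self.order_, self.coef_, self.residuals_ = best
        return self

    def transform(self, X=None):
        return self.residuals_


def fit_binary_residuals(series) -> DetrendModel:
    """Serial logistic detrending of a binary-dominant series."""
    est = BinaryLogisticDetrender().fit(series)
    return DetrendModel("binary-logistic", (est.order_,), est.aic_, est.residuals_)


def detrend(series) -> DetrendModel:
    """Detrend a series, with the residual-worse fallback.

    Dispatches on the 75%-zeros rule to ARIMA or the serial logistic model;
    if |lag-1 autocorrelation| of the residuals exceeds that of the raw
    series, the raw series (mean-centered for the continuous case) is
    returned as ``kind='passthrough'``.
    """
    s = _as_series(series)
    model = fit_binary_residuals(s) if is_binary_dominant(s) else fit_arima_residuals(s)
    if abs(lag1_autocorrelation(model.residuals)) > abs(lag1_autocorrelation(s)):
        return DetrendModel("passthrough", (), np.nan, s - s.mean())
    return model
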