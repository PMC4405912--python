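"""Robust regression-based normalization with bacterial-load inference.

Standard sum-to-one normalization suffers compositional artifacts: if one
taxon blooms, every other taxon's *fraction* drops even when its absolute
abundance did not change.  The approach implemented here assumes that at
least half of the abundant OTUs shared by two communities are unchanged, and
uses outlier-robust statistics to find the median fold-change ``m`` between
an observed day ``x`` and a reference community ``y`` (modelling
``y_i = m_i x_i`` per OTU and taking the median ``m_i``).  Rescaling a day's
fractions by its ``m`` removes the compositional artifact, and because
rescaled days no longer sum to one, ``m`` itself tracks relative total
bacterial load.

Procedure per day:

1. restrict to abundant OTUs — the smallest abundance-sorted prefix covering
   90% of the median daily fractions;
2. build a reference community as the per-OTU weighted median of fractions
   across all days, weighting day ``t`` by ``(1 - j)**2`` where ``j`` is the
   Jensen-Shannon distance from the target day to ``t``;
3. fit ``m`` in log10 space (abundance data are heteroscedastic):
   ``m = 10**median(log10 y_i - log10 x_i)`` over OTUs nonzero in both;
4. discard days whose fit is uncertain: median absolute log10 residual
   greater than 0.4 (about 2.5-fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_io import OtuTimeSeries
from .stability import _jsd_matrix_from_fractions, fractional_normalize


@dataclass
class NormalizationModel:
    """Per-day fit diagnostics from robust normalization."""

    abundant_otus: pd.Index
    reference: pd.DataFrame  # (days x abundant OTUs) reference fractions
    weights: pd.DataFrame  # (target day x source day) (1-j)^2 weights
    m: pd.Series  # per-day scaling factor (relative load)
    residual_spread: pd.Series  # per-day median |log10 residual|
    discard_threshold: float
    kept: pd.Series  # boolean per day


@dataclass
class NormalizationResult:
    """Rescaled abundances and inferred relative load for kept days."""

    rescaled: pd.DataFrame  # m * fractions, kept days only; rows need not sum to 1
    load: pd.Series  # inferred relative load (= m) for kept days
    discarded_days: list
    model: NormalizationModel


def select_abundant_otus(series: OtuTimeSeries, coverage: float = 0.9) -> pd.Index:
    """Abundance-sorted prefix of OTUs covering ``coverage`` of the summed
    per-OTU median daily fractions."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if series.fractions is None:
        series = fractional_normalize(series)
    medians = series.fractions.median(axis=0)
    total = medians.sum()
    if total <= 0:
        raise ValueError("all OTU median fractions are zero")
    order = medians.sort_values(ascending=False, kind="stable")
    csum = order.cumsum()
    k = int(np.searchsorted(csum.to_numpy(), coverage * total - 1e-12)) + 1
    chosen = order.index[:k]
    return chosen[order.loc[chosen] > 0]


def weighted_median(values, weights) -> float:
    """Lower weighted median: the smallest value whose cumulative normalized
    weight reaches 0.5."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / w.sum()
    return float(v[order][np.searchsorted(cum, 0.5 - 1e-12)])


def _weighted_median_columns(values: np.ndarray, weights: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Column-wise lower weighted median; ``order`` is argsort(values, axis=0)."""
    w = weights[order]
    cum = np.cumsum(w, axis=0) / w.sum(axis=0, keepdims=True)
    idx = (cum >= 0.5 - 1e-12).argmax(axis=0)
    cols = np.arange(values.shape[1])
    return values[order[idx, cols], cols]


def reference_community(
    series: OtuTimeSeries,
    target_day: int,
    abundant_otus: pd.Index | None = None,
):
    """Reference fractions for one day and the day weights used to build it.

    Weight of day ``t`` is ``(1 - JSD(target, t))**2``; the target itself
    gets weight 1.  The reference value for OTU ``i`` is the weighted median
    of its fraction across all days.
    """
    if series.fractions is None:
        series = fractional_normalize(series)
    if abundant_otus is None:
        abundant_otus = select_abundant_otus(series)
    jsd = _jsd_matrix_from_fractions(series.fractions)
    w = (1.0 - jsd.loc[target_day]) ** 2
    sub = series.fractions[abundant_otus]
    vals = sub.to_numpy()
    order = np.argsort(vals, axis=0, kind="stable")
    ref = _weighted_median_columns(vals, w.to_numpy(), order)
    return pd.Series(ref, index=abundant_otus, name=target_day), w


def robust_scaling_factor(x, y) -> tuple[float, float]:
    """Robust per-day scaling factor between observed ``x`` and reference
    ``y`` over shared abundant OTUs.

    Returns ``(m, residual_spread)`` with ``m = 10**median(log10 y - log10 x)``
    and the spread the median absolute log10 residual about the fit.  Pairs
    where either side is zero are dropped; fewer than 3 usable pairs is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable OTU pairs; m undefined")
    logr = np.log10(y[ok]) - np.log10(x[ok])
    med = np.median(logr)
    return float(10.0 ** med), float(np.median(np.abs(logr - med)))


class RobustLoadNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for robust load normalization.

    ``fit`` takes a (days x OTUs) matrix of fractional abundances (rows
    summing to 1) and infers per-day scaling factors against weighted-median
    reference communities built from the fitted data; ``transform`` rescales
    rows by their factor.  Rows seen at ``fit`` time participate in their own
    reference with weight 1; new rows passed to ``transform`` are normalized
    against the fitted days only.

    Parameters
    ----------
    coverage : float, default 0.9
        Median-fraction coverage used to pick the abundant OTU subset.
    discard_threshold : float, default 0.4
        Maximum median absolute log10 residual for a day to be kept.

    Attributes
    ----------
    abundant_otus_ : pandas.Index
    load_ : pandas.Series       — inferred relative load per fitted day
    residual_spread_ : pandas.Series
    kept_ : pandas.Series       — boolean, spread <= discard_threshold
    reference_ : pandas.DataFrame
    """

    def __init__(self, coverage: float = 0.9, discard_threshold: float = 0.4):
        self.coverage = coverage
        self.discard_threshold = discard_threshold

    def fit(self, X, y=None):
        X = self._as_frame(X)
        series = OtuTimeSeries(
            counts=pd.DataFrame(0, index=X.index, columns=X.columns, dtype=np.int64),
            fractions=X,
        )
        self.fractions_ = X
        self.abundant_otus_ = select_abundant_otus(series, self.coverage)
        jsd = _jsd_matrix_from_fractions(X)
        weights = (1.0 - jsd) ** 2
        sub = X[self.abundant_otus_].to_numpy()
        order = np.argsort(sub, axis=0, kind="stable")
        refs, ms, spreads = [], [], []
        for k, day in enumerate(X.index):
            ref = _weighted_median_columns(sub, weights.to_numpy()[k], order)
            m, spread = robust_scaling_factor(sub[k], ref)
            refs.append(ref)
            ms.append(m)
            spreads.append(spread)
        self.reference_ = pd.DataFrame(refs, index=X.index, columns=self.abundant_otus_)
        self.weights_ = weights
        self.load_ = pd.Series(ms, index=X.index, name="load")
        self.residual_spread_ = pd.Series(spreads, index=X.index, name="spread")
        self.kept_ = self.residual_spread_ <= self.discard_threshold
        if not self.kept_.any():
            raise ValueError("every day was discarded by the spread rule")
        return self

    def transform(self, X):
        X = self._as_frame(X)
        if X.index.equals(self.fractions_.index):
            m = self.load_
        else:
            m = pd.Series(
                [self._factor_for_row(row) for _, row in X.iterrows()], index=X.index
            )
        return X.mul(m, axis=0)

    def _factor_for_row(self, row: pd.Series) -> float:
        from .stability import jensen_shannon_distance

        sub = self.fractions_[self.abundant_otus_].to_numpy()
        order = np.argsort(sub, axis=0, kind="stable")
        w = np.array(
            [
                (1.0 - jensen_shannon_distance(row.to_numpy(), f)) ** 2
                for f in self.fractions_.to_numpy()
            ]
        )
        ref = _weighted_median_columns(sub, w, order)
        m, _ = robust_scaling_factor(row[self.abundant_otus_].to_numpy(), ref)
        return m

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        X = pd.DataFrame(X).astype(float)
        if (X.to_numpy() < 0).any():
            raise ValueError("fractions must be non-negative")
        return X


def robust_normalize(
    series: OtuTimeSeries,
    coverage: float = 0.9,
    discard_threshold: float = 0.4,
) -> NormalizationResult:
    """Run robust load normalization over a QC'd OTU time series.

    Returns rescaled abundances (``m * fractions``, all OTUs) and the
    inferred relative load series for kept days; days failing the residual
    spread rule are listed in ``discarded_days``.
    """
    if series.fractions is None:
        series = fractional_normalize(series)
    est = RobustLoadNormalizer(coverage=coverage, discard_threshold=discard_threshold).fit(
        series.fractions
    )
    kept_days = est.kept_.index[est.kept_]
    rescaled = series.fractions.loc[kept_days].mul(est.load_.loc[kept_days], axis=0)
    model = NormalizationModel(
        abundant_otus=est.abundant_otus_,
        reference=est.reference_,
        weights=est.weights_,
        m=est.load_,
        residual_spread=est.residual_spread_,
        discard_threshold=discard_threshold,
        kept=est.kept_,
    )
    return NormalizationResult(
        rescaled=rescaled,
        load=est.load_.loc[kept_days],
        discarded_days=est.kept_.index[~est.kept_].tolist(),
        model=model,
    )
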