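"""Lagged association between host metadata and OTU-cluster dynamics.

Detrended metadata and detrended cluster series are cross-correlated
(Spearman) at lags from -7 to +7 days.  A positive lag means the microbiota
follows the metadata: at lag L the metadata value on day t is paired with
the cluster value on day t + L, so "fiber at lag +1" reads "bacterial
abundance shifts one day after the fiber change".  Guard rails against
spurious time-series correlations: series with residual lag-1
autocorrelation at p < 0.01 are excluded up front; q-values are
Benjamini-Hochberg, computed separately within each (lag, body site)
family; significant pairs whose mutual regression shows autocorrelated
errors (Durbin-Watson permutation p < 0.01) are excluded afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import SpearmanWpgmaClusterer, cluster_median_series
from .data_io import MetadataSeries, OtuTimeSeries
from .detrending import detrend, lag1_autocorrelation
from .stability import fractional_normalize


@dataclass
class AssociationRecord:
    """One (metadata variable, OTU cluster, lag) correlation test."""

    variable: str
    cluster: object
    lag: int
    rho: float
    p_value: float
    n_pairs: int
    body_site: str = ""
    q_value: float | None = None
    autocorr_excluded: bool = False
    dw_excluded: bool = False

    @property
    def excluded(self) -> bool:
        return self.autocorr_excluded or self.dw_excluded


def otu_prevalence_filter(series: OtuTimeSeries, min_presence: float = 0.5) -> OtuTimeSeries:
    """Keep OTUs detected on at least ``min_presence`` of days (inclusive)."""
    present = (series.counts > 0).mean(axis=0)
    keep = series.counts.columns[present >= min_presence]
    from dataclasses import replace

    return replace(
        series,
        counts=series.counts[keep],
        fractions=None if series.fractions is None else
        series.fractions[keep].div(series.fractions[keep].sum(axis=1), axis=0),
        taxonomy=None if series.taxonomy is None else series.taxonomy.loc[keep],
    )


def autocorrelation_screen(series, alpha: float = 0.01) -> tuple[bool, float]:
    """Exclude series with significant residual lag-1 autocorrelation.

    Returns ``(keep, p_value)``; the test is the normal approximation
    ``z = r1 * sqrt(n)``.  Series with fewer than 10 points or no variation
    are excluded conservatively.
    """
    v = pd.Series(series).dropna().to_numpy(dtype=float)
    if v.size < 10 or np.ptp(v) == 0:
        return False, 0.0
    r1 = lag1_autocorrelation(v)
    z = r1 * np.sqrt(v.size)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return p >= alpha, p


def lagged_spearman(
    metadata_residuals: pd.Series,
    cluster_residuals: pd.DataFrame | pd.Series,
    lags=range(-7, 8),
    min_overlap: int = 30,
    variable: str = "",
    body_site: str = "",
) -> list[AssociationRecord]:
    """Spearman correlation at each lag between a metadata residual series
    and each cluster residual series.

    At lag L, metadata(t) is paired with cluster(t + L) on shared dates;
    lags with fewer than ``min_overlap`` pairs are omitted.
    """
    if isinstance(cluster_residuals, pd.Series):
        cluster_residuals = cluster_residuals.to_frame(
            cluster_residuals.name if cluster_residuals.name is not None else 0
        )
    meta = metadata_residuals.dropna()
    records = []
    for col in cluster_residuals.columns:
        clus = cluster_residuals[col].dropna()
        for L in lags:
            shifted = clus.copy()
            shifted.index = shifted.index - L  # value at t+L becomes usable at t
            joined = pd.concat([meta, shifted], axis=1, join="inner").dropna()
            if len(joined) < min_overlap:
                continue
            rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
            if np.isnan(rho):
                continue
            records.append(
                AssociationRecord(
                    variable=variable,
                    cluster=col,
                    lag=int(L),
                    rho=float(rho),
                    p_value=float(p),
                    n_pairs=len(joined),
                    body_site=body_site,
                )
            )
    return records


def fdr_by_family(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Benjamini-Hochberg q-values computed separately per (lag, body site).

    Records carrying an exclusion flag take no part and receive no q-value.
    """
    eligible = [r for r in records if not r.excluded]
    families: dict[tuple, list[AssociationRecord]] = {}
    for r in eligible:
        families.setdefault((r.lag, r.body_site), []).append(r)
    for fam in families.values():
        pvals = np.array([r.p_value for r in fam])
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        for r, qv in zip(fam, q):
            r.q_value = float(qv)
    return records


def durbin_watson_screen(
    metadata_residuals: pd.Series,
    cluster_residuals: pd.Series,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed=None,
) -> tuple[bool, float, float]:
    """Exclude pairs whose mutual regression has autocorrelated errors.

    OLS of the cluster residuals on the metadata residuals; the
    Durbin-Watson statistic of the regression errors is compared against a
    permutation null (errors in shuffled time order), two-sided.  Returns
    ``(keep, dw, p_value)``; fewer than 20 aligned points excludes
    conservatively.
    """
    joined = pd.concat([metadata_residuals, cluster_residuals], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 20:
        return False, np.nan, 0.0
    x = joined.iloc[:, 0].to_numpy(dtype=float)
    y = joined.iloc[:, 1].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    dw = _dw_stat(e)
    rng = np.random.default_rng(seed)
    null = np.array([_dw_stat(rng.permutation(e)) for _ in range(n_permutations)])
    lo = (np.sum(null <= dw) + 1) / (n_permutations + 1)
    hi = (np.sum(null >= dw) + 1) / (n_permutations + 1)
    p = float(min(1.0, 2.0 * min(lo, hi)))
    return p >= alpha, float(dw), p


def _dw_stat(e: np.ndarray) -> float:
    return float(np.sum(np.diff(e) ** 2) / np.sum(e**2))


@dataclass
class AssociationResult:
    """Pipeline output: all records plus the screening bookkeeping."""

    records: list[AssociationRecord]
    cluster_assignment: object
    screened_out_variables: list[str] = field(default_factory=list)
    screened_out_clusters: list = field(default_factory=list)

    def significant(self, q_threshold: float = 0.05) -> list[AssociationRecord]:
        return [
            r
            for r in self.records
            if not r.excluded and r.q_value is not None and r.q_value < q_threshold
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "cluster": r.cluster,
                    "lag": r.lag,
                    "rho": r.rho,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "n_pairs": r.n_pairs,
                    "body_site": r.body_site,
                    "autocorr_excluded": r.autocorr_excluded,
                    "dw_excluded": r.dw_excluded,
                }
                for r in self.records
            ]
        )


def run_association_pipeline(
    series: OtuTimeSeries,
    metadata: list[MetadataSeries],
    min_presence: float = 0.5,
    threshold_fraction: float = 0.8,
    lags=range(-7, 8),
    screen_alpha: float = 0.01,
    dw_alpha: float = 0.01,
    q_threshold: float = 0.05,
    min_overlap: int = 30,
    dw_screen: bool = True,
    dw_permutations: int = 1000,
    seed=None,
) -> AssociationResult:
    """Full host-factor/microbiota association pipeline.

    Prevalence-filter OTUs -> log10 abundances (detection-limit floored) ->
    ARIMA-detrend each OTU -> cluster residuals (Spearman + WPGMA, 80% cut)
    -> per-cluster median series, detrended again -> autocorrelation screen
    -> lagged Spearman against each detrended metadata variable -> BH FDR
    per (lag, body site) -> Durbin-Watson screen on significant pairs.
    """
    filtered = otu_prevalence_filter(series, min_presence)
    filtered = fractional_normalize(filtered)
    logab = np.log10(filtered.fractions.clip(lower=series.detection_limit))
    resid = {}
    for otu in logab.columns:
        resid[otu] = detrend(logab[otu]).residuals
    resid = pd.DataFrame(resid)
    clusterer = SpearmanWpgmaClusterer(threshold_fraction=threshold_fraction).fit(resid)
    assignment = clusterer.assignment_
    medians = cluster_median_series(resid, assignment)
    # the median of whitened members can itself pick up serial structure
    # (e.g. a shared ARMA leftover), so cluster series are detrended again
    medians = pd.DataFrame({c: detrend(medians[c].dropna()).residuals for c in medians})

    screened_clusters = []
    keep_cols = []
    for col in medians.columns:
        keep, _ = autocorrelation_screen(medians[col].dropna(), alpha=screen_alpha)
        (keep_cols if keep else screened_clusters).append(col)
    medians = medians[keep_cols]

    rng = np.random.default_rng(seed)
    records: list[AssociationRecord] = []
    screened_vars = []
    meta_resid: dict[str, pd.Series] = {}
    for var in metadata:
        model = detrend(var.values)
        keep, _ = autocorrelation_screen(model.residuals, alpha=screen_alpha)
        if not keep:
            screened_vars.append(var.name)
            continue
        meta_resid[var.name] = model.residuals
        records.extend(
            lagged_spearman(
                model.residuals,
                medians,
                lags=lags,
                min_overlap=min_overlap,
                variable=var.name,
                body_site=series.body_site,
            )
        )
    fdr_by_family(records)
    for r in records:
        if dw_screen and r.q_value is not None and r.q_value < q_threshold:
            clus = medians[r.cluster].copy()
            clus.index = clus.index - r.lag
            keep, dw, p = durbin_watson_screen(
                meta_resid[r.variable],
                clus,
                alpha=dw_alpha,
                n_permutations=dw_permutations,
                seed=rng.integers(2**31 - 1),
            )
            if not keep:
                r.dw_excluded = True
    return AssociationResult(
        records=records,
        cluster_assignment=assignment,
        screened_out_variables=screened_vars,
        screened_out_clusters=screened_clusters,
    )
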