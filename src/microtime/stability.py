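"""Community-level stability metrics.

Jensen-Shannon distance (JSD) between daily communities, full pairwise JSD
matrices, median-JSD-versus-temporal-separation curves (an asymptoting curve
indicates a stable community), core-OTU persistence, and phylum-level
abundance ratios such as Bacteroidetes/Firmicutes.

JSD here is the square root of the Jensen-Shannon divergence with base-2
logarithms: a true metric bounded by 1, which is what the (1 - j)^2 reference
weights in :mod:`microtime.normalization` require.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import entropy

from .data_io import OtuTimeSeries


def fractional_normalize(series: OtuTimeSeries) -> OtuTimeSeries:
    """Standard normalization: convert each day's counts to fractions
    summing to one."""
    totals = series.counts.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total day(s) {bad}; run sample QC first")
    fractions = series.counts.div(totals, axis=0)
    return replace(series, fractions=fractions)


def jensen_shannon_distance(p, q) -> float:
    """JSD between two probability vectors (base-2, square-rooted, in [0,1])."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must sum to 1")
    d = float(jensenshannon(p, q, base=2))
    return 0.0 if np.isnan(d) else min(d, 1.0)


def jsd_matrix(series: OtuTimeSeries) -> pd.DataFrame:
    """All pairwise JSDs between days, as a symmetric labelled matrix."""
    if series.fractions is None:
        series = fractional_normalize(series)
    return _jsd_matrix_from_fractions(series.fractions)


def _jsd_matrix_from_fractions(fractions: pd.DataFrame) -> pd.DataFrame:
    p = fractions.to_numpy(dtype=float)
    n = p.shape[0]
    if n < 2:
        raise ValueError("need at least 2 days for a distance matrix")
    # Vectorized JS divergence: JS(p,q) = H(m) - (H(p)+H(q))/2, base 2.
    h = entropy(p, base=2, axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        m = 0.5 * (p[i] + p[i + 1 :])
        js = entropy(m, base=2, axis=1) - 0.5 * (h[i] + h[i + 1 :])
        out[i, i + 1 :] = js
    out = out + out.T
    np.sqrt(np.clip(out, 0.0, 1.0), out=out)
    return pd.DataFrame(out, index=fractions.index, columns=fractions.index)


def median_jsd_vs_separation(matrix: pd.DataFrame, max_lag: int | None = None) -> pd.Series:
    """Median pairwise JSD as a function of temporal separation in days.

    Separations with no sample pair are omitted.  For a stable community the
    curve asymptotes near the overall median; sustained growth with
    separation indicates drift.
    """
    days = np.asarray(matrix.index, dtype=int)
    vals = matrix.to_numpy()
    i, j = np.triu_indices(len(days), k=1)
    sep = days[j] - days[i]
    if max_lag is not None:
        keep = sep <= max_lag
        sep, d = sep[keep], vals[i[keep], j[keep]]
    else:
        d = vals[i, j]
    curve = pd.Series(d).groupby(sep).median()
    curve.index.name = "separation_days"
    return curve


def core_otus(series: OtuTimeSeries, presence_fraction: float = 0.95):
    """OTUs detected on at least ``presence_fraction`` of days, and the
    fraction of all reads they account for."""
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must be in (0, 1]")
    present = (series.counts > 0).mean(axis=0)
    core = series.counts.columns[present >= presence_fraction]
    total = series.counts.to_numpy().sum()
    frac = float(series.counts[core].to_numpy().sum() / total) if total else 0.0
    return core, frac


def _rank_token(taxonomy: str, rank: str) -> str | None:
    """Extract a rank (e.g. 'phylum') from a lineage string, accepting both
    Greengenes-style 'p__Firmicutes' tokens and plain semicolon lineages."""
    prefix = {"kingdom": "k__", "phylum": "p__", "class": "c__", "order": "o__",
              "family": "f__", "genus": "g__", "species": "s__"}[rank]
    parts = [t.strip() for t in str(taxonomy).split(";")]
    for t in parts:
        if t.startswith(prefix):
            return t[len(prefix):] or None
    pos = list(prefix_order()).index(rank)
    if len(parts) > pos and not any("__" in t for t in parts):
        return parts[pos] or None
    return None


def prefix_order():
    return ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def phylum_ratio(
    series: OtuTimeSeries,
    numerator_phylum: str,
    denominator_phylum: str,
    rank: str = "phylum",
) -> pd.Series:
    """Per-day ratio of two phyla's summed fractional abundances.

    Days where the denominator phylum is absent yield NaN rather than an
    error.
    """
    if series.taxonomy is None:
        raise ValueError("series has no taxonomy")
    if series.fractions is None:
        series = fractional_normalize(series)
    phyla = series.taxonomy.map(lambda t: _rank_token(t, rank))
    num = series.fractions.loc[:, (phyla == numerator_phylum).to_numpy()].sum(axis=1)
    den = series.fractions.loc[:, (phyla == denominator_phylum).to_numpy()].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den.replace(0.0, np.nan)
    ratio.name = f"{numerator_phylum}/{denominator_phylum}"
    return ratio
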