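"""Stationarity screening of OTU trajectories and phylogenetic clustering
of the non-stationary ones.

An OTU whose abundance reverts to an equilibrium after fluctuations is
stationary; sustained drift (e.g. competitive exclusion) is not.  The
augmented Dickey-Fuller (ADF) test is run on log10, mean-centered series
with no deterministic trend, lag order chosen by the t-statistic rule.
Because the equilibrium level is estimated from the data (the centering),
p-values come from the Dickey-Fuller distribution that accounts for an
estimated mean; pairing the centered series with the zero-mean null
distribution would reject ~30% of true random walks at alpha = 0.05
instead of 5%.  Rejection of the unit-root null (p < alpha) marks the OTU
stationary.

Whether non-stationary OTUs cluster on a reference phylogeny — as expected
if closely related taxa compete — is assessed with the P-test: the Fitch
(Hartigan) parsimony score of the stationary/non-stationary labelling on the
tree, compared with its distribution under random leaf-label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode
from statsmodels.tsa.stattools import adfuller

from .data_io import OtuTimeSeries
from .stability import fractional_normalize


@dataclass
class StationarityResult:
    otu_id: str
    adf_statistic: float
    p_value: float
    n_lags: int
    stationary: bool
    alpha: float = 0.05


def adf_test(
    series,
    alpha: float = 0.05,
    detection_limit: float = 10.0 ** -5.8,
    otu_id: str = "",
) -> StationarityResult:
    """ADF unit-root test on a positive abundance series.

    Zeros (and values below the detection limit) are floored at the
    detection limit before the log10 transform; the series is then
    mean-centered and tested with no deterministic trend, t-stat lag
    selection up to ``floor(12 * (n/100)**0.25)`` lags, and the
    estimated-mean (drift-form) null distribution, which is calibrated for
    series whose equilibrium level was estimated from the data.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 20:
        raise ValueError("series too short for the ADF test (need >= 20)")
    if (x < 0).any():
        raise ValueError("series must be non-negative")
    x = np.log10(np.maximum(x, detection_limit))
    if np.ptp(x) == 0:
        raise ValueError("constant series; ADF regression is degenerate")
    x = x - x.mean()
    maxlag = int(np.floor(12.0 * (x.size / 100.0) ** 0.25))
    maxlag = min(maxlag, x.size // 2 - 2)
    stat, pval, usedlag, *_ = adfuller(x, maxlag=maxlag, regression="c", autolag="t-stat")
    return StationarityResult(
        otu_id=otu_id,
        adf_statistic=float(stat),
        p_value=float(pval),
        n_lags=int(usedlag),
        stationary=bool(pval < alpha),
        alpha=alpha,
    )


def stationary_fraction(
    series: OtuTimeSeries,
    window: tuple[int, int] | None = None,
    top_n: int = 100,
    alpha: float = 0.05,
):
    """Fraction of the ``top_n`` most abundant OTUs in a date window that
    are stationary (ADF p < alpha), plus the per-OTU results.

    OTUs whose series degenerate (constant after flooring) are excluded
    from the fraction with a warning.
    """
    if series.fractions is None:
        series = fractional_normalize(series)
    frac = series.fractions
    if window is not None:
        lo, hi = window
        frac = frac.loc[(frac.index >= lo) & (frac.index <= hi)]
    mean_ab = frac.mean(axis=0).sort_values(ascending=False, kind="stable")
    if len(mean_ab) < top_n:
        warnings.warn(
            f"only {len(mean_ab)} OTUs available; using all", stacklevel=2
        )
    chosen = mean_ab.index[:top_n]
    results: dict[str, StationarityResult] = {}
    for otu in chosen:
        try:
            results[otu] = adf_test(
                frac[otu].to_numpy(),
                alpha=alpha,
                detection_limit=series.detection_limit,
                otu_id=str(otu),
            )
        except ValueError as exc:
            warnings.warn(f"skipping OTU {otu}: {exc}", stacklevel=2)
    if not results:
        raise ValueError("no testable OTU in window")
    fraction = float(np.mean([r.stationary for r in results.values()]))
    return fraction, results


def fitch_parsimony(tree: TreeNode, labels: dict) -> int:
    """Minimum number of label changes on the tree (Fitch; Hartigan's
    generalization for multifurcating nodes).

    ``labels`` maps tip name -> hashable state for every tip of ``tree``.
    """
    changes = 0
    states: dict[int, frozenset] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name not in labels:
                raise ValueError(f"tip {node.name!r} has no label")
            states[id(node)] = frozenset([labels[node.name]])
        else:
            counts: dict = {}
            for child in node.children:
                for s in states[id(child)]:
                    counts[s] = counts.get(s, 0) + 1
            top = max(counts.values())
            states[id(node)] = frozenset(s for s, c in counts.items() if c == top)
            changes += len(node.children) - top
    return changes


def p_test(
    phylogeny: TreeNode,
    labels: dict,
    n_permutations: int = 1000,
    seed=None,
) -> tuple[float, int]:
    """Permutation P-test for phylogenetic clustering of a binary label.

    The observed parsimony score of ``labels`` on the tree (restricted to
    the labelled tips) is compared with scores under random permutations of
    the labels across tips; the corrected p-value is
    ``(#{null <= observed} + 1) / (n_permutations + 1)``.  Small p means the
    classes change state on the tree less often than chance, i.e. they
    cluster phylogenetically.
    """
    tips = [t.name for t in phylogeny.tips() if t.name in labels]
    if len(tips) < 4:
        raise ValueError("need at least 4 labelled tips")
    values = [labels[t] for t in tips]
    if len(set(values)) < 2:
        raise ValueError("both classes must be present")
    sub = phylogeny.shear(tips) if len(tips) < phylogeny.count(tips=True) else phylogeny
    observed = fitch_parsimony(sub, labels)
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=object)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        if fitch_parsimony(sub, dict(zip(tips, perm))) <= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1), observed
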