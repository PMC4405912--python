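"""Grouping OTUs by shared temporal dynamics.

Pairwise distances are ``max(0, 1 - rho)`` with rho the Spearman
correlation of two OTU series on their shared dates; the distance matrix is
agglomerated with WPGMA ('weighted') linkage and cut into flat clusters at
a fraction (80% for association work, 90% for disturbance work) of the
maximum merge height.  Cluster dynamics are summarized by the per-date
median over member OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class ClusterAssignment:
    """Flat OTU clustering with its cut parameters."""

    labels: pd.Series  # otu_id -> cluster label (1-based, deterministic order)
    threshold_fraction: float
    cut_height: float
    linkage_matrix: np.ndarray | None = None

    def members(self, label) -> pd.Index:
        return self.labels.index[self.labels == label]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def spearman_distance_matrix(series_set: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """``max(0, 1 - rho)`` Spearman distances between the columns of a
    (dates x OTUs) frame, computed on pairwise-shared non-missing dates."""
    if series_set.shape[1] < 2:
        raise ValueError("need at least 2 series")
    X = series_set.to_numpy(dtype=float)
    if not np.isnan(X).any():
        if X.shape[0] < min_overlap:
            raise ValueError("insufficient overlap between series")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(X).statistic
        if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case
            rho = np.array([[1.0, rho], [rho, 1.0]])
    else:
        n = X.shape[1]
        rho = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
                if ok.sum() < min_overlap:
                    raise ValueError(
                        f"insufficient overlap between series {i} and {j}"
                    )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho[i, j] = rho[j, i] = spearmanr(X[ok, i], X[ok, j]).statistic
    rho = np.nan_to_num(rho, nan=0.0)  # a constant series is uncorrelated
    dist = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=series_set.columns, columns=series_set.columns)


class SpearmanWpgmaClusterer(BaseEstimator, ClusterMixin):
    """WPGMA clustering of OTU series on Spearman distances.

    ``fit`` takes a (dates x OTUs) frame; ``labels_`` maps each OTU to a
    1-based cluster label, relabelled deterministically by first member.
    The flat cut is at ``threshold_fraction`` times the maximum merge
    height.
    """

    def __init__(self, threshold_fraction: float = 0.8):
        self.threshold_fraction = threshold_fraction

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        dist = spearman_distance_matrix(X)
        self.assignment_ = hierarchical_clusters(dist, self.threshold_fraction)
        self.labels_ = self.assignment_.labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def hierarchical_clusters(
    dist_matrix: pd.DataFrame, threshold_fraction: float = 0.8
) -> ClusterAssignment:
    """Cut a WPGMA dendrogram of the distance matrix at
    ``threshold_fraction`` of its maximum merge height."""
    ids = dist_matrix.index
    if len(ids) == 1:
        return ClusterAssignment(
            labels=pd.Series([1], index=ids), threshold_fraction=threshold_fraction,
            cut_height=0.0,
        )
    condensed = squareform(dist_matrix.to_numpy(), checks=False)
    Z = linkage(condensed, method="weighted")
    cut = threshold_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(_relabel_by_first_member(raw), index=ids)
    return ClusterAssignment(
        labels=labels,
        threshold_fraction=threshold_fraction,
        cut_height=float(cut),
        linkage_matrix=Z,
    )


def _relabel_by_first_member(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[lab] for lab in raw])


def cluster_median_series(
    series_set: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Per-cluster median over member OTUs at each date
    (dates x clusters)."""
    out = {}
    for label in sorted(assignment.labels.unique()):
        members = assignment.members(label)
        members = members.intersection(series_set.columns)
        if len(members) == 0:
            warnings.warn(f"cluster {label} has no series; skipped", stacklevel=2)
            continue
        out[label] = series_set[members].median(axis=1)
    return pd.DataFrame(out)
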