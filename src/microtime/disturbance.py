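"""Community response to major perturbations (travel, enteric infection).

Given a perturbation window, OTUs that were core beforehand are classified
by their fate (retained / lost / extinct / gained), dominant cluster
trajectories are identified, phylogenetic coherence of clusters is tested
with a subtree-collapsed Fisher exact test (collapsing near-identical
same-cluster leaves guards against strain-level sequencing artifacts
inflating significance), and host metadata are checked for pre/post
distribution shifts with Mann-Whitney U tests under BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterAssignment
from .data_io import MetadataSeries, OtuTimeSeries
from .stability import fractional_normalize


@dataclass
class DisturbanceSummary:
    """Fate of pre-perturbation core OTUs across a window."""

    window: tuple[int, int]
    pre_median: pd.Series  # per-OTU median fraction before the window
    post_median: pd.Series  # per-OTU median fraction after the window
    retained: pd.Index  # pre-core, post median > 0
    lost: pd.Index  # pre-core, post median == 0
    extinct: pd.Index  # lost and never detected again after the window
    gained: pd.Index  # post-core OTUs absent (median 0) pre-window
    category_read_fraction: pd.DataFrame  # per window segment, per category


def pre_post_summary(
    series: OtuTimeSeries,
    window: tuple[int, int],
    presence_fraction: float = 0.95,
) -> DisturbanceSummary:
    """Categorize core OTUs by their fate across a perturbation window."""
    if series.fractions is None:
        series = fractional_normalize(series)
    start, end = window
    pre = series.fractions.loc[series.fractions.index < start]
    post = series.fractions.loc[series.fractions.index > end]
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("empty pre or post segment")
    pre_counts = series.counts.loc[series.counts.index < start]
    post_counts = series.counts.loc[series.counts.index > end]
    pre_core = pre_counts.columns[(pre_counts > 0).mean(axis=0) >= presence_fraction]
    post_core = post_counts.columns[(post_counts > 0).mean(axis=0) >= presence_fraction]
    pre_median = pre.median(axis=0)
    post_median = post.median(axis=0)
    lost = pre_core[post_median.loc[pre_core] == 0]
    retained = pre_core[post_median.loc[pre_core] > 0]
    never_again = post_counts.columns[(post_counts == 0).all(axis=0)]
    extinct = lost.intersection(never_again)
    gained = post_core[pre_median.loc[post_core] == 0]
    cat = {}
    for name, seg in (("pre", pre), ("post", post)):
        total = seg.to_numpy().sum()
        other = seg.columns.difference(retained.union(lost).union(gained))
        cat[name] = {
            "retained": seg[retained].to_numpy().sum() / total,
            "lost": seg[lost].to_numpy().sum() / total,
            "gained": seg[gained.difference(retained).difference(lost)].to_numpy().sum() / total,
            "other": seg[other].to_numpy().sum() / total,
        }
    return DisturbanceSummary(
        window=window,
        pre_median=pre_median,
        post_median=post_median,
        retained=retained,
        lost=lost,
        extinct=extinct,
        gained=gained,
        category_read_fraction=pd.DataFrame(cat).T,
    )


def major_clusters(cluster_series: pd.DataFrame, min_fraction: float = 0.10,
                   min_days: int = 3) -> list:
    """Clusters whose summed fractional abundance exceeds ``min_fraction``
    on strictly more than ``min_days`` distinct days."""
    days_above = (cluster_series > min_fraction).sum(axis=0)
    return [c for c in cluster_series.columns if days_above[c] > min_days]


def _subtree_diameter(node: TreeNode) -> float:
    tips = list(node.tips())
    if len(tips) < 2:
        return 0.0
    dm = node.tip_tip_distances()
    return float(np.max(dm.data))


def collapse_tree(
    phylogeny: TreeNode,
    assignment: ClusterAssignment | pd.Series | dict,
    max_leaf_distance: float = 0.2,
) -> TreeNode:
    """Collapse maximal subtrees of same-cluster, near-identical leaves.

    A subtree collapses to a single representative leaf when all its leaves
    share one cluster assignment and every pairwise patristic distance is
    below ``max_leaf_distance``.  Idempotent.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else pd.Series(assignment)
    tree = phylogeny.copy()

    def collapsible(node: TreeNode) -> bool:
        tips = list(node.tips())
        if len(tips) < 2:
            return False
        names = [t.name for t in tips]
        if any(n not in labels.index for n in names):
            return False
        if labels.loc[names].nunique() > 1:
            return False
        return _subtree_diameter(node) < max_leaf_distance

    changed = True
    while changed:
        changed = False
        for node in tree.levelorder(include_self=True):
            if not node.is_tip() and collapsible(node):
                rep = next(node.tips()).name
                for child in list(node.children):
                    node.remove(child)
                node.name = rep
                changed = True
                break
    return tree


def cluster_subtree_fisher(
    collapsed_phylogeny: TreeNode,
    assignment: ClusterAssignment | pd.Series | dict,
    focal_clusters,
    subtree_node: TreeNode | str,
) -> tuple[float, float, np.ndarray]:
    """Two-sided Fisher exact test for enrichment of focal clusters inside
    a subtree of the collapsed phylogeny.

    The 2x2 table counts collapsed leaves by (in/out of the focal cluster
    set) x (inside/outside the subtree).  Returns
    ``(odds_ratio, p, table)``.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else pd.Series(assignment)
    if isinstance(subtree_node, str):
        subtree_node = collapsed_phylogeny.find(subtree_node)
    all_leaves = [t.name for t in collapsed_phylogeny.tips() if t.name in labels.index]
    inside = {t.name for t in subtree_node.tips() if t.name in labels.index}
    focal = set(np.atleast_1d(np.asarray(focal_clusters, dtype=object)))
    in_focal = {n for n in all_leaves if labels.loc[n] in focal}
    a = len(inside & in_focal)
    b = len(in_focal - inside)
    c = len(inside - in_focal)
    d = len(all_leaves) - a - b - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError(f"degenerate contingency table {table.tolist()}")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def scan_subtrees(
    collapsed_phylogeny: TreeNode,
    assignment,
    focal_clusters,
    min_leaves: int = 3,
) -> pd.DataFrame:
    """Exploratory scan of every internal node's Fisher test, with
    Bonferroni-adjusted p-values (exploratory; the rule selecting which
    subtree to report must come from the analyst)."""
    rows = []
    for i, node in enumerate(collapsed_phylogeny.non_tips(include_self=True)):
        if sum(1 for _ in node.tips()) < min_leaves:
            continue
        try:
            odds, p, table = cluster_subtree_fisher(
                collapsed_phylogeny, assignment, focal_clusters, node
            )
        except ValueError:
            continue
        rows.append({"node": node.name or f"internal_{i}", "odds_ratio": odds,
                     "p_value": p, "n_inside": int(table[0, 0] + table[1, 0])})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


def pre_post_metadata_shift(
    metadata: list[MetadataSeries],
    window: tuple[int, int],
    span_days: int = 30,
) -> pd.DataFrame:
    """Mann-Whitney U pre/post comparison of each metadata variable around
    a perturbation window, BH-corrected across variables.

    Variables missing on either side, or with a single shared value, are
    skipped.
    """
    start, end = window
    rows = []
    for var in metadata:
        v = var.values.dropna()
        pre = v[(v.index >= start - span_days) & (v.index < start)]
        post = v[(v.index > end) & (v.index <= end + span_days)]
        if len(pre) == 0 or len(post) == 0:
            continue
        if pd.concat([pre, post]).nunique() <= 1:
            continue
        u, p = stats.mannwhitneyu(pre, post, alternative="two-sided")
        rows.append({"variable": var.name, "U": float(u), "p_value": float(p),
                     "n_pre": len(pre), "n_post": len(post)})
    df = pd.DataFrame(rows)
    if len(df):
        _, q, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["q_value"] = q
    return df
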