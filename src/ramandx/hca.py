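"""Hierarchical cluster analysis of per-biopsy mean chemical-score profiles.

Each biopsy is summarized by the mean effective score of the selected
chemicals across its spectra; biopsies are then clustered agglomeratively
(Euclidean distance, average linkage — the usual clustergram default) and
the profile is rendered as a 5-level binned "pixel chart" matrix, mirroring
how biochemical expression profiles are typically displayed alongside the
dendrogram.  Because chemical scores live on very different scales, each
chemical column is standardized before distances are computed (the same
convention clustergram/heatmap tools apply); pass ``standardize=False`` for
raw-score distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomerative merge history over biopsy profiles."""

    merges: np.ndarray           # scipy linkage matrix, (n-1) × 4
    leaf_order: list[int]
    leaf_labels: list[str]
    two_cluster_labels: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def last_merged_leaf(self) -> str | None:
        """The single biopsy joining the tree at the final merge, if any.

        Returns ``None`` when the last merge joins two multi-leaf clusters.
        """
        n = self.n_leaves
        a, b = int(self.merges[-1, 0]), int(self.merges[-1, 1])
        if a < n:
            return self.leaf_labels[a]
        if b < n:
            return self.leaf_labels[b]
        return None

    def leaf_attachment_heights(self) -> dict[str, float]:
        """Height at which each biopsy first joins any cluster.

        The biopsy with the greatest attachment height is the one least
        similar to every other profile.
        """
        n = self.n_leaves
        heights: dict[str, float] = {}
        for a, b, h, _size in self.merges:
            for node in (int(a), int(b)):
                if node < n:
                    heights[self.leaf_labels[node]] = float(h)
        return heights

    def least_similar_leaf(self) -> str:
        heights = self.leaf_attachment_heights()
        return max(heights, key=heights.get)

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.leaf_labels[i] for i in range(n)}
        for m, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + m] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + m] = h
        return nodes[n + self.merges.shape[0] - 1] + ";"


def mean_scores_by_biopsy(
    score_table: pd.DataFrame, selected: list[str]
) -> pd.DataFrame:
    """Mean effective score per biopsy for the selected chemicals.

    Returns a DataFrame indexed by biopsy_id with one column per chemical.
    """
    missing = [c for c in selected if c not in score_table.columns]
    if missing:
        raise ValidationError(f"unknown chemicals: {missing}")
    if "biopsy_id" not in score_table.columns:
        raise ValidationError("score table lacks a biopsy_id column")
    return score_table.groupby("biopsy_id")[list(selected)].mean()


def cluster(
    means: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    standardize: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of biopsy profiles with a two-cluster cut."""
    M = means.to_numpy(dtype=float)
    if M.shape[0] < 2:
        raise ValidationError("need at least 2 biopsies to cluster")
    if np.any(~np.isfinite(M)):
        raise ValidationError("mean scores contain NaN or infinite values")
    if standardize:
        sd = M.std(axis=0)
        sd[sd == 0] = 1.0
        M = (M - M.mean(axis=0)) / sd
    Z = linkage(M, method=method, metric=metric)
    cut = fcluster(Z, t=2, criterion="maxclust")
    return Dendrogram(
        merges=Z,
        leaf_order=[int(i) for i in leaves_list(Z)],
        leaf_labels=[str(i) for i in means.index],
        two_cluster_labels=cut,
    )


def bin_scores(means: pd.DataFrame, levels: int = 5) -> pd.DataFrame:
    """Equal-width per-chemical binning of mean scores into ``levels`` bins.

    Column-wise: the minimum maps to bin 0 and the maximum to ``levels - 1``.
    A constant column is degenerate and maps to the middle bin with a warning.
    """
    M = means.to_numpy(dtype=float)
    if np.any(~np.isfinite(M)):
        raise ValidationError("mean scores contain NaN or infinite values")
    out = np.empty_like(M, dtype=int)
    for j in range(M.shape[1]):
        col = M[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            logger.warning(
                "bin_scores: constant column %r assigned the middle bin",
                means.columns[j],
            )
            out[:, j] = levels // 2
            continue
        bins = np.floor((col - lo) / (hi - lo) * levels).astype(int)
        out[:, j] = np.clip(bins, 0, levels - 1)
    return pd.DataFrame(out, index=means.index, columns=means.columns)
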