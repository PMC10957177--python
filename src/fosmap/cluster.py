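"""Hierarchical clustering of regions by drug response.

Regions are clustered by complete linkage on Euclidean distances
between their per-animal log-relative density profiles.  Cuts are
expressed as a ratio of the maximum merge height; a merge is applied
iff its height <= ratio * max height, so ratio 1.0 always yields one
cluster and the cluster count is non-increasing in the ratio.

Silhouette coefficients follow the standard conventions: singleton
clusters score 0, and a 0/0 (all points coincident) scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "Dendrogram",
    "feature_matrix",
    "complete_linkage",
    "cut_at_height",
    "cut_at_ratio",
    "silhouette_samples",
    "mean_silhouette",
    "silhouette_curve",
    "cluster_count_curve",
    "cluster_summary",
    "to_newick",
    "ResponseClustering",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dendrogram:
    """A complete-linkage merge tree over labelled leaves."""

    linkage: np.ndarray = field(repr=False)  # scipy (n-1, 4) linkage matrix
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (max(n - 1, 0), 4):
            raise ValueError("linkage shape inconsistent with number of leaves")
        h = self.heights
        if len(h) and np.any(np.diff(h) < 0):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.heights[-1]) if len(self.heights) else 0.0

    def leaf_order(self) -> list[str]:
        if self.n_leaves == 1:
            return list(self.labels)
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]


def feature_matrix(logrel: pd.DataFrame, collapse: str = "animals") -> pd.DataFrame:
    """Prepare the regions x animals clustering features.

    All-missing rows are dropped (logged); remaining missing cells are
    imputed by the region's row mean.  ``collapse="mean"`` reduces the
    columns to the per-region mean profile.
    """
    if collapse not in ("animals", "mean"):
        raise ValueError("collapse must be 'animals' or 'mean'")
    X = logrel.copy()
    empty = X.index[X.isna().all(axis=1)]
    if len(empty):
        logger.warning("dropping %d all-missing region(s): %s", len(empty), list(empty[:5]))
        X = X.drop(index=empty)
    X = X.apply(lambda row: row.fillna(row.mean()), axis=1)
    if collapse == "mean":
        X = X.mean(axis=1).to_frame("mean")
    return X


def complete_linkage(dist: pd.DataFrame | np.ndarray, labels=None) -> Dendrogram:
    """Complete-linkage dendrogram from a square distance matrix.

    At each step the pair of clusters with the smallest maximum
    inter-cluster pairwise distance is merged, so merge heights are
    non-decreasing.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index) if labels is None else list(labels)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        labels = [str(i) for i in range(len(D))] if labels is None else list(labels)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if len(labels) == 1:
        return Dendrogram(np.empty((0, 4)), tuple(labels))
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    return Dendrogram(Z, tuple(labels))


def _labels_from_cut(dend: Dendrogram, cut_height: float) -> pd.Series:
    """Apply merges with height <= cut_height; renumber clusters 1..k in
    dendrogram leaf order."""
    n = dend.n_leaves
    # scipy node ids: leaves are 0..n-1, merge m creates node n+m
    parent: dict[int, int] = {}

    def find(i: int) -> int:
        while i in parent:
            i = parent[i]
        return i

    for m, (a, b, h, _) in enumerate(dend.linkage):
        if h <= cut_height:
            parent[int(a)] = n + m
            parent[int(b)] = n + m
    leaf_roots = [find(i) for i in range(n)]
    label_pos = {lab: i for i, lab in enumerate(dend.labels)}
    ids: dict[int, int] = {}
    for lab in dend.leaf_order():
        root = leaf_roots[label_pos[lab]]
        if root not in ids:
            ids[root] = len(ids) + 1
    return pd.Series([ids[leaf_roots[i]] for i in range(n)], index=list(dend.labels), name="cluster")


def cut_at_height(dend: Dendrogram, height: float) -> pd.Series:
    """Cluster labels after applying every merge with height <= *height*."""
    return _labels_from_cut(dend, float(height))


def cut_at_ratio(dend: Dendrogram, ratio: float) -> pd.Series:
    """Cluster labels at cut height = ratio * maximum merge height.

    Requires 0 < ratio <= 1.  Cluster ids are 1..k in dendrogram leaf
    order, so labels are reproducible across runs.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    return _labels_from_cut(dend, ratio * dend.max_height)


def silhouette_samples(dist: np.ndarray | pd.DataFrame, labels) -> np.ndarray:
    """Per-point silhouette s = (b - a) / max(a, b) from a square
    distance matrix.

    a is the mean intra-cluster distance (excluding self), b the
    smallest mean distance to another cluster.  Singletons score 0, as
    does the degenerate a = b = 0 case.
    """
    D = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    s = np.zeros(n)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    sums = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        if sizes[ci] == 1:
            continue
        a = sums[i, ci] / (sizes[ci] - 1)
        other = [sums[i, cj] / sizes[cj] for cj in range(len(uniq)) if cj != ci]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def mean_silhouette(dist, labels) -> float:
    return float(np.mean(silhouette_samples(dist, labels)))


def silhouette_curve(dist, dend: Dendrogram, ratios) -> pd.DataFrame:
    """(ratio, k, mean silhouette) table over dendrogram cut ratios.

    The silhouette is missing where the cut yields a single cluster.
    """
    rows = []
    for r in ratios:
        labels = cut_at_ratio(dend, r)
        k = labels.nunique()
        sil = mean_silhouette(dist, labels.to_numpy()) if k >= 2 else np.nan
        rows.append((r, k, sil))
    return pd.DataFrame(rows, columns=["ratio", "k", "silhouette"])


def cluster_count_curve(dend: Dendrogram, ratios) -> pd.DataFrame:
    """(ratio, k) pairs; k is non-increasing as the ratio grows."""
    rows = [(r, cut_at_ratio(dend, r).nunique()) for r in ratios]
    return pd.DataFrame(rows, columns=["ratio", "k"])


def cluster_summary(labels: pd.Series, z_values: pd.Series) -> dict:
    """Per-cluster mean +/- SEM of Z values, one-way ANOVA across
    clusters and Tukey HSD pairwise comparisons.

    Regions without a Z value are excluded; clusters of size 1 appear in
    the summary but are excluded from the ANOVA/Tukey (logged).
    """
    z = z_values.reindex(labels.index)
    keep = z.notna()
    if (~keep).any():
        logger.warning("excluding %d region(s) without Z value from cluster summary", int((~keep).sum()))
    labels, z = labels[keep], z[keep]
    summary = (
        pd.DataFrame({"cluster": labels, "z": z})
        .groupby("cluster")["z"]
        .agg(n="size", mean_z="mean", sem_z=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    groups = {c: z[labels == c].to_numpy() for c in summary["cluster"]}
    eligible = {c: v for c, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(eligible))
    if dropped:
        logger.warning("cluster(s) %s have a single member; excluded from ANOVA", dropped)
    result: dict = {"summary": summary, "anova_F": np.nan, "anova_p": np.nan, "tukey": None}
    if len(eligible) >= 2:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance clusters
            F, p = stats.f_oneway(*eligible.values())
            result["anova_F"], result["anova_p"] = float(F), float(p)
            tk = stats.tukey_hsd(*eligible.values())
        names = list(eligible)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    (
                        names[i],
                        names[j],
                        float(tk.statistic[i, j]),
                        float(tk.pvalue[i, j]),
                    )
                )
        result["tukey"] = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "mean_diff", "p_adj"])
    return result


def to_newick(dend: Dendrogram) -> str:
    """Newick export with branch lengths = height differences."""
    if dend.n_leaves == 1:
        return f"{dend.labels[0]};"
    tree = hierarchy.to_tree(dend.linkage)

    def rec(node, parent_height: float | None) -> str:
        if node.is_leaf():
            body = dend.labels[node.id]
        else:
            body = f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.dist:g}"

    return rec(tree, None) + ";"


class ResponseClustering(BaseEstimator, ClusterMixin):
    """Complete-linkage clustering of regions by response profile.

    Parameters
    ----------
    cut_ratio : float, default 0.5
        Dendrogram cut as a ratio of the maximum merge height.
    features : {"animals", "mean"}, default "animals"
        Cluster on per-animal profiles or on the per-region mean.

    Attributes (after :meth:`fit`)
    ------------------------------
    features_ : imputed feature matrix actually clustered
    distances_ : square Euclidean distance DataFrame
    dendrogram_ : :class:`Dendrogram`
    labels_ : ndarray of cluster ids aligned with ``features_.index``
    k_ : number of clusters
    silhouette_ : mean silhouette at the cut (NaN if k < 2)
    """

    def __init__(self, cut_ratio: float = 0.5, features: str = "animals"):
        self.cut_ratio = cut_ratio
        self.features = features

    def fit(self, X: pd.DataFrame, y=None) -> "ResponseClustering":
        if not 0 < self.cut_ratio <= 1:
            raise ValueError("cut_ratio must be in (0, 1]")
        feats = feature_matrix(pd.DataFrame(X), collapse=self.features)
        feats = feats.sort_index()
        D = squareform(pdist(feats.to_numpy(float)))
        self.features_ = feats
        self.distances_ = pd.DataFrame(D, index=feats.index, columns=feats.index)
        self.dendrogram_ = complete_linkage(self.distances_)
        lab = cut_at_ratio(self.dendrogram_, self.cut_ratio)
        self.labels_by_region_ = lab
        self.labels_ = lab.to_numpy()
        self.k_ = int(lab.nunique())
        self.silhouette_ = (
            mean_silhouette(self.distances_, self.labels_) if self.k_ >= 2 else float("nan")
        )
        return self

    def silhouette_curve(self, ratios) -> pd.DataFrame:
        return silhouette_curve(self.distances_, self.dendrogram_, ratios)

    def count_curve(self, ratios) -> pd.DataFrame:
        return cluster_count_curve(self.dendrogram_, ratios)

    def summarize(self, z_values: pd.Series) -> dict:
        return cluster_summary(self.labels_by_region_, z_values)
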