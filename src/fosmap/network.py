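"""Interregional correlation networks and hub identification.

Each group's functional network is built from Pearson correlations of
ln c-Fos densities across animals: an edge joins two regions when the
correlation both exceeds a threshold (r >= 0.82 by default) and is
significantly positive at a one-tailed level (t-test with n-2 df,
alpha = 0.05, uncorrected).  Edges keep r as their weight.  Modules
come from complete-linkage clustering of 1 - r distances; hubs are the
nodes ranking in the top quantile of degree, betweenness and
eigenvector centrality simultaneously.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import cluster as _cluster

__all__ = [
    "CorrelationMatrix",
    "interregional_correlation",
    "fisher_z",
    "inverse_fisher",
    "compare_mean_correlation",
    "one_tailed_r_pvalue",
    "threshold_network",
    "network_density",
    "detect_modules",
    "centrality_table",
    "identify_hubs",
    "read_correlation_csv",
    "write_correlation_csv",
    "CorrelationNetwork",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations of ln densities across subjects in one group.

    ``r`` is symmetric with unit diagonal; ``n`` holds the per-pair
    subject count actually used (pairwise-complete observations).
    """

    r: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.r.index) != list(self.r.columns):
            raise ValueError("correlation matrix must have matching index and columns")

    @property
    def regions(self) -> list[str]:
        return list(self.r.index)


def interregional_correlation(
    lnd: pd.DataFrame,
    regions=None,
    min_subjects: int = 3,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations of a subjects x regions
    ln-density table.

    Pairs with fewer than *min_subjects* shared observations, and
    regions constant across subjects, yield missing entries (logged).
    """
    X = lnd if regions is None else lnd.reindex(columns=list(regions))
    r = X.corr(method="pearson", min_periods=min_subjects)
    notna = X.notna().astype(int)
    n = notna.T @ notna
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        logger.warning("constant region vector(s), correlations undefined: %s", constant[:5])
        r.loc[constant, :] = np.nan
        r.loc[:, constant] = np.nan
    np.fill_diagonal(r.to_numpy(), 1.0)
    missing = int(np.isnan(r.to_numpy()[np.triu_indices(len(r), 1)]).sum())
    if missing:
        logger.warning("%d missing correlation entr(ies)", missing)
    return CorrelationMatrix(r, n.astype(float))


def fisher_z(r):
    """Fisher transformation z = atanh(r); |r| = 1 is an error."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transformation")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _upper_entries(mat: CorrelationMatrix | pd.DataFrame) -> np.ndarray:
    r = mat.r if isinstance(mat, CorrelationMatrix) else mat
    vals = r.to_numpy(dtype=float)[np.triu_indices(len(r), 1)]
    vals = vals[~np.isnan(vals)]
    excl = np.abs(vals) >= 1
    if excl.any():
        logger.warning("excluding %d |r|=1 entr(ies) from Fisher comparison", int(excl.sum()))
    return vals[~excl]


def compare_mean_correlation(mat_a, mat_b) -> tuple[float, float]:
    """Two-sample z comparison of mean Fisher-transformed correlations.

    Returns (signed z, two-sided p); positive z means A exceeds B.
    """
    za, zb = np.arctanh(_upper_entries(mat_a)), np.arctanh(_upper_entries(mat_b))
    diff = za.mean() - zb.mean()
    se = math.sqrt(np.var(za, ddof=1) / len(za) + np.var(zb, ddof=1) / len(zb))
    if se == 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def one_tailed_r_pvalue(r: float, n: int) -> float:
    """One-tailed p for H1: rho > 0, via t = r sqrt((n-2)/(1-r^2)), df n-2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(stats.t.sf(t, n - 2))


def threshold_network(
    mat: CorrelationMatrix,
    r_min: float = 0.82,
    alpha: float = 0.05,
) -> nx.Graph:
    """Weighted undirected network: edge (i, j) iff r_ij >= r_min AND the
    one-tailed p < alpha.  Isolated regions stay in the node set;
    missing entries count as no edge (logged)."""
    regions = mat.regions
    G = nx.Graph(r_min=float(r_min), alpha=float(alpha))
    G.add_nodes_from(regions)
    R = mat.r.to_numpy(dtype=float)
    N = mat.n.to_numpy(dtype=float)
    skipped = 0
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            r = R[i, j]
            if np.isnan(r):
                skipped += 1
                continue
            n = int(N[i, j])
            if r >= r_min and n >= 3 and abs(r) < 1 and one_tailed_r_pvalue(r, n) < alpha:
                G.add_edge(regions[i], regions[j], weight=float(r))
            elif r >= 1:  # perfect correlation: significant by construction
                G.add_edge(regions[i], regions[j], weight=1.0)
    if skipped:
        logger.warning("%d missing correlation entr(ies) treated as non-edges", skipped)
    return G


def network_density(G: nx.Graph) -> float:
    """2|E| / (|V| (|V|-1))."""
    if G.number_of_nodes() < 2:
        raise ValueError("density needs at least 2 nodes")
    return float(nx.density(G))


def detect_modules(
    mat: CorrelationMatrix | pd.DataFrame,
    cut: float = 0.7,
    absolute: bool = False,
) -> pd.Series:
    """Module labels from complete-linkage clustering of 1 - r distances.

    *cut* is a ratio of the maximum merge height by default; with
    ``absolute=True`` it is an absolute height on the 1 - r scale.
    Missing correlations are imputed as r = 0 (logged).
    """
    r = (mat.r if isinstance(mat, CorrelationMatrix) else mat).copy()
    if r.isna().to_numpy().any():
        logger.warning("imputing missing correlations as r=0 for module detection")
        r = r.fillna(0.0)
    D = 1.0 - r.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    dend = _cluster.complete_linkage(pd.DataFrame(D, index=r.index, columns=r.index))
    if absolute:
        return _cluster.cut_at_height(dend, cut)
    return _cluster.cut_at_ratio(dend, cut)


def _eigenvector(G: nx.Graph) -> pd.Series:
    """Principal eigenvector of the weighted adjacency of the largest
    connected component (ties broken toward the lexicographically
    smallest member); other nodes score 0.  Non-negative, unit 2-norm."""
    ev = pd.Series(0.0, index=list(G.nodes))
    comps = [sorted(c) for c in nx.connected_components(G) if len(c) > 1]
    if not comps:
        return ev
    comp = sorted(comps, key=lambda c: (-len(c), str(c[0])))[0]
    cent = nx.eigenvector_centrality(G.subgraph(comp), weight="weight", max_iter=10000, tol=1e-12)
    vec = np.array([cent[v] for v in comp])
    vec = np.abs(vec) / np.linalg.norm(vec)
    ev[comp] = vec
    return ev


def centrality_table(G: nx.Graph, length: str = "inverse") -> pd.DataFrame:
    """Degree, weighted strength, betweenness and eigenvector centrality.

    Degree is the unweighted edge count.  Betweenness uses shortest
    paths with edge length 1/weight (``length="one_minus"`` switches to
    1 - weight) and the (|V|-1)(|V|-2)/2 normalization.  Eigenvector
    centrality lives on the largest connected component.
    """
    if length not in ("inverse", "one_minus"):
        raise ValueError("length must be 'inverse' or 'one_minus'")
    nodes = list(G.nodes)
    if G.number_of_edges() == 0:
        zero = np.zeros(len(nodes))
        return pd.DataFrame(
            {"degree": zero.astype(int), "strength": zero, "betweenness": zero, "eigenvector": zero},
            index=nodes,
        )
    H = G.copy()
    for u, v, d in H.edges(data=True):
        w = d["weight"]
        d["length"] = (1.0 / w) if length == "inverse" else (1.0 - w)
    btw = nx.betweenness_centrality(H, weight="length", normalized=True)
    return pd.DataFrame(
        {
            "degree": pd.Series(dict(G.degree()), dtype=int),
            "strength": pd.Series(dict(G.degree(weight="weight")), dtype=float),
            "betweenness": pd.Series(btw, dtype=float),
            "eigenvector": _eigenvector(G),
        }
    ).loc[nodes]


def identify_hubs(centralities: pd.DataFrame, quantile: float = 0.80) -> set[str]:
    """Hubs: nodes at or above the top-(1-quantile) rank cut in degree,
    betweenness AND eigenvector centrality.

    Ranks are computed over nodes with degree >= 1; the cut keeps the
    ceil((1-quantile) * m) largest values with boundary ties included.
    Fewer than 5 connected nodes yields an empty set (warning).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    connected = centralities[centralities["degree"] >= 1]
    m = len(connected)
    if m < 5:
        logger.warning("only %d connected node(s); no hubs called", m)
        return set()
    k = math.ceil((1 - quantile) * m)
    hubs = set(connected.index)
    n_degenerate = 0
    for measure in ("degree", "betweenness", "eigenvector"):
        vals = connected[measure].to_numpy(dtype=float)
        thr = np.sort(vals)[::-1][k - 1]
        n_degenerate += int(np.allclose(vals, vals[0]))
        # boundary ties included, with a small tolerance for float jitter
        hubs &= set(connected.index[connected[measure] >= thr - 1e-9])
    if n_degenerate == 3:
        logger.warning("degenerate centralities (all nodes tie in all measures); hub call is uninformative")
    return hubs


def read_correlation_csv(path) -> CorrelationMatrix:
    """Square correlation CSV with region-acronym headers; the per-pair
    n is unknown for such files and set to NaN."""
    r = pd.read_csv(path, index_col=0)
    r.index = r.index.astype(str)
    n = pd.DataFrame(np.nan, index=r.index, columns=r.columns)
    return CorrelationMatrix(r, n)


def write_correlation_csv(mat: CorrelationMatrix, path) -> None:
    mat.r.to_csv(path)


def export_graphml(G: nx.Graph, centralities: pd.DataFrame, modules: pd.Series, hubs: set, path) -> None:
    H = G.copy()
    for v in H.nodes:
        H.nodes[v]["degree"] = int(centralities.loc[v, "degree"])
        H.nodes[v]["betweenness"] = float(centralities.loc[v, "betweenness"])
        H.nodes[v]["eigenvector"] = float(centralities.loc[v, "eigenvector"])
        H.nodes[v]["module"] = int(modules.get(v, -1))
        H.nodes[v]["hub"] = bool(v in hubs)
    nx.write_graphml(H, path)


def export_edgelist(G: nx.Graph, path) -> None:
    rows = [(u, v, d["weight"]) for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


class CorrelationNetwork(BaseEstimator):
    """Functional network for one group from a subjects x regions
    ln-density table.

    Parameters
    ----------
    r_min : float, default 0.82
        Minimum Pearson r for an edge.
    alpha : float, default 0.05
        One-tailed significance level for the edge test.
    module_cut : float, default 0.7
        Dendrogram cut (ratio of max height, or absolute height on the
        1 - r scale when ``absolute_cut=True``) for module labels.
    hub_quantile : float, default 0.80
        Rank quantile a hub must reach in all three centralities.
    length : {"inverse", "one_minus"}, default "inverse"
        Edge length convention for betweenness shortest paths.

    Attributes (after :meth:`fit`)
    ------------------------------
    correlation_ : :class:`CorrelationMatrix`
    graph_ : networkx.Graph (edge weight = r)
    density_ : float
    modules_ : Series region -> module id
    n_modules_ : int
    centralities_ : DataFrame (degree, strength, betweenness, eigenvector, hub)
    hubs_ : set of region acronyms
    """

    def __init__(
        self,
        r_min: float = 0.82,
        alpha: float = 0.05,
        module_cut: float = 0.7,
        absolute_cut: bool = False,
        hub_quantile: float = 0.80,
        length: str = "inverse",
    ):
        self.r_min = r_min
        self.alpha = alpha
        self.module_cut = module_cut
        self.absolute_cut = absolute_cut
        self.hub_quantile = hub_quantile
        self.length = length

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationNetwork":
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must be in [-1, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        X = pd.DataFrame(X).sort_index(axis=1)
        self.correlation_ = interregional_correlation(X)
        self.graph_ = threshold_network(self.correlation_, r_min=self.r_min, alpha=self.alpha)
        self.density_ = network_density(self.graph_)
        self.modules_ = detect_modules(self.correlation_, cut=self.module_cut, absolute=self.absolute_cut)
        self.n_modules_ = int(self.modules_.nunique())
        cent = centrality_table(self.graph_, length=self.length)
        self.hubs_ = identify_hubs(cent, quantile=self.hub_quantile)
        cent["hub"] = cent.index.isin(self.hubs_)
        self.centralities_ = cent
        return self
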