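"""Bacterial co-abundance network inference and reduction.

The network is inferred over differentially abundant taxa from their
normalized abundance profiles:

1. pairwise mutual information (MI), estimated by equal-frequency
   discretization with Miller-Madow bias correction;
2. C3NET — after multiple-testing correction against a permutation
   null, each taxon contributes the edge to its maximum-MI significant
   partner;
3. BC3NET — a bagging ensemble of C3NET over bootstrap resamples of the
   samples, with a binomial test on edge support;
4. MST2 — union of the network's minimum spanning tree and the minimum
   spanning tree of the remainder, a sparse backbone that highlights
   central nodes;
5. hubs — nodes whose degree strictly exceeds the 95th percentile of the
   degree distribution.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .differential import bh_adjust

__all__ = [
    "estimate_mi",
    "mi_matrix",
    "permutation_null_mi",
    "c3net_core",
    "c3net",
    "bc3net",
    "mst2_reduce",
    "network_stats",
    "select_hubs",
    "Mst2Tree",
    "HubReport",
]

_LN2 = math.log(2.0)


def _equal_freq_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin index per observation (stable ties)."""
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    """Plug-in MI (bits) with Miller-Madow correction from bin indices."""
    n = bx.size
    joint = np.bincount(bx * bins + by, minlength=bins * bins).astype(float)
    joint /= n
    px = np.bincount(bx, minlength=bins).astype(float) / n
    py = np.bincount(by, minlength=bins).astype(float) / n
    nz_j = joint > 0
    nz_x = px > 0
    nz_y = py > 0
    h_x = -np.sum(px[nz_x] * np.log(px[nz_x]))
    h_y = -np.sum(py[nz_y] * np.log(py[nz_y]))
    h_xy = -np.sum(joint[nz_j] * np.log(joint[nz_j]))
    mi = h_x + h_y - h_xy
    # Miller-Madow: H_mm = H + (K-1)/(2n) per entropy term
    corr = (nz_x.sum() - 1 + nz_y.sum() - 1 - (nz_j.sum() - 1)) / (2.0 * n)
    return max(0.0, (mi + corr) / _LN2)


def estimate_mi(x, y, bins: int | None = None) -> float:
    """Mutual information in bits between two abundance profiles.

    Both vectors are discretized into ``bins`` equal-frequency bins
    (default ceil(sqrt(n))); the plug-in estimate is Miller-Madow bias
    corrected and clamped at 0.  Constant vectors give MI = 0 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: MI set to 0", stacklevel=2)
        return 0.0
    if bins is None:
        bins = math.ceil(math.sqrt(n))
    return _mi_from_bins(_equal_freq_bins(x, bins), _equal_freq_bins(y, bins), bins)


def mi_matrix(data: pd.DataFrame, bins: int | None = None) -> pd.DataFrame:
    """Symmetric pairwise MI matrix over the rows of ``data`` (taxa x samples)."""
    n = data.shape[1]
    if bins is None:
        bins = math.ceil(math.sqrt(n))
    X = data.to_numpy(dtype=float)
    B = np.vstack([_equal_freq_bins(X[i], bins) for i in range(X.shape[0])])
    const = np.array([np.ptp(X[i]) == 0 for i in range(X.shape[0])])
    m = X.shape[0]
    out = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        if const[i] or const[j]:
            continue
        out[i, j] = out[j, i] = _mi_from_bins(B[i], B[j], bins)
    return pd.DataFrame(out, index=data.index, columns=data.index)


def permutation_null_mi(
    data: pd.DataFrame, n_perm: int = 1000, bins: int | None = None, rng=None
) -> np.ndarray:
    """Pooled null MI values from random row pairs with one row permuted."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = data.to_numpy(dtype=float)
    m, n = X.shape
    if bins is None:
        bins = math.ceil(math.sqrt(n))
    B = np.vstack([_equal_freq_bins(X[i], bins) for i in range(m)])
    out = np.empty(n_perm)
    for k in range(n_perm):
        i, j = rng.integers(m), rng.integers(m)
        perm = rng.permutation(n)
        out[k] = _mi_from_bins(B[i], B[j][perm], bins)
    return out


def c3net_core(mi: pd.DataFrame, significant: pd.DataFrame) -> set[tuple[str, str]]:
    """The C3NET selection rule given MI and a significance mask.

    Each node contributes the edge to its maximum-MI significant partner
    (ties broken by label order); the result is the deduplicated union.
    """
    nodes = list(mi.index)
    edges: set[tuple[str, str]] = set()
    M = mi.to_numpy(dtype=float)
    S = significant.to_numpy(dtype=bool)
    for i, u in enumerate(nodes):
        best_j = -1
        best = -1.0
        for j in range(len(nodes)):
            if j == i or not S[i, j]:
                continue
            if M[i, j] > best:
                best = M[i, j]
                best_j = j
        if best_j >= 0:
            v = nodes[best_j]
            edges.add((u, v) if u <= v else (v, u))
    return edges


def c3net(
    data: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    bins: int | None = None,
    rng=None,
) -> nx.Graph:
    """C3NET inference from an abundance matrix (taxa x samples).

    Pair significance: the MI of each pair is compared against a pooled
    permutation null; the per-pair empirical p-values are BH-corrected and
    pairs with q < alpha count as significant.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mi = mi_matrix(data, bins=bins)
    null = permutation_null_mi(data, n_perm=n_perm, bins=bins, rng=rng)
    nodes = list(mi.index)
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    M = mi.to_numpy()
    null_sorted = np.sort(null)
    pvals = [
        (1.0 + null.size - np.searchsorted(null_sorted, M[i, j], side="left"))
        / (1.0 + null.size)
        for i, j in pairs
    ]
    qvals = bh_adjust(pvals)
    sig = np.zeros_like(M, dtype=bool)
    for (i, j), q in zip(pairs, qvals):
        sig[i, j] = sig[j, i] = q < alpha
    edges = c3net_core(mi, pd.DataFrame(sig, index=nodes, columns=nodes))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, weight=float(mi.loc[u, v]))
    return g


def bc3net(
    data: pd.DataFrame,
    B: int = 100,
    alpha_ind: float = 0.05,
    alpha_ens: float = 0.05,
    n_perm: int = 1000,
    bins: int | None = None,
    seed=None,
    bootstrap: bool = True,
) -> nx.Graph:
    """BC3NET: bagged C3NET over bootstrap resamples of the samples.

    ``B`` C3NET networks are inferred from column-resampled data; an
    edge's ensemble support count is tested against Binomial(B, p0) with
    p0 = 1/#pairs (the expected null edge rate), BH-corrected at
    ``alpha_ens``.  Surviving edges are weighted by their support
    fraction.  ``bootstrap=False`` is a diagnostic that disables
    resampling (with B=1 this reduces to plain C3NET).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if data.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = data.shape[1]
    support: dict[tuple[str, str], int] = {}
    mi_sum: dict[tuple[str, str], float] = {}
    for _ in range(B):
        if bootstrap:
            cols = rng.integers(0, n, size=n)
            sub = pd.DataFrame(
                data.to_numpy()[:, cols], index=data.index
            )
        else:
            sub = data
        g_b = c3net(sub, alpha=alpha_ind, n_perm=n_perm, bins=bins, rng=rng)
        for u, v, w in g_b.edges(data="weight"):
            key = (u, v) if u <= v else (v, u)
            support[key] = support.get(key, 0) + 1
            mi_sum[key] = mi_sum.get(key, 0.0) + w
    g = nx.Graph()
    g.add_nodes_from(data.index)
    if not support:
        return g
    m = data.shape[0]
    p0 = 1.0 / (m * (m - 1) / 2)
    keys = sorted(support)
    from scipy.stats import binom

    pvals = [float(binom.sf(support[k] - 1, B, p0)) for k in keys]
    qvals = bh_adjust(pvals)
    for k, q in zip(keys, qvals):
        if q < alpha_ens:
            g.add_edge(
                *k,
                weight=support[k] / B,
                support=support[k],
                mean_mi=mi_sum[k] / support[k],
            )
    return g


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def _kruskal(nodes, edges) -> set[tuple[str, str]]:
    """Minimum spanning forest; ``edges`` pre-sorted by (distance, u, v)."""
    uf = _UnionFind(nodes)
    chosen = set()
    for _, u, v in edges:
        if uf.union(u, v):
            chosen.add((u, v))
    return chosen


@dataclass
class Mst2Tree:
    """MST2 backbone: MST1 plus the MST of the graph minus MST1 edges."""

    graph: nx.Graph
    mst1_edges: set[tuple[str, str]]
    second_edges: set[tuple[str, str]]


def mst2_reduce(net: nx.Graph, weight: str = "weight") -> Mst2Tree:
    """Reduce a weighted network to its MST2 backbone.

    Edge distance is ``w_max - w`` so the strongest associations are the
    shortest; per connected component, MST1 is the minimum spanning tree
    and the second tree is the minimum spanning forest of the component
    with MST1 edges removed (nodes kept).  Ties break lexicographically
    on the sorted node pair.
    """
    if net.number_of_edges() == 0:
        return Mst2Tree(graph=net.copy(), mst1_edges=set(), second_edges=set())
    w_max = max(w for _, _, w in net.edges(data=weight))
    edges = sorted(
        (w_max - w, *sorted((u, v)))
        for u, v, w in net.edges(data=weight)
    )
    nodes = list(net.nodes)
    mst1 = _kruskal(nodes, edges)
    rest = [e for e in edges if (e[1], e[2]) not in mst1]
    mst2nd = _kruskal(nodes, rest)
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for u, v in mst1 | mst2nd:
        g.add_edge(u, v, **net.edges[u, v],
                   in_mst1=(u, v) in mst1, in_mst2=(u, v) in mst2nd)
    return Mst2Tree(graph=g, mst1_edges=mst1, second_edges=mst2nd)


def network_stats(net: nx.Graph) -> dict:
    """Topology summary: giant-component size, mean degree and betweenness.

    Mean degree is 2|E|/|V| over the giant component; betweenness is
    unnormalized shortest-path betweenness (unweighted paths, endpoints
    excluded) averaged over giant-component nodes; ``n_isolated`` counts
    nodes outside the giant component.
    """
    n_nodes = net.number_of_nodes()
    if n_nodes == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "giant_size": 0, "n_isolated": 0,
            "avg_degree": 0.0, "avg_betweenness": 0.0,
        }
    comps = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    giant = net.subgraph(comps[0])
    bc = nx.betweenness_centrality(giant, normalized=False)
    return {
        "n_nodes": n_nodes,
        "n_edges": net.number_of_edges(),
        "giant_size": giant.number_of_nodes(),
        "n_isolated": n_nodes - giant.number_of_nodes(),
        "avg_degree": 2.0 * giant.number_of_edges() / giant.number_of_nodes(),
        "avg_betweenness": float(np.mean(list(bc.values()))),
    }


@dataclass
class HubReport:
    """Hub nodes: degree strictly above the interpolated degree percentile."""

    threshold: float
    percentile: float
    table: pd.DataFrame  # taxon, degree, betweenness; degree-descending


def select_hubs(net: nx.Graph, percentile: float = 95.0) -> HubReport:
    """Nodes whose degree strictly exceeds the given degree percentile.

    The threshold uses linear interpolation between order statistics over
    the full node set (isolated nodes count with degree 0), so it can be
    non-integer; the strict inequality means an all-equal degree sequence
    yields no hubs.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    degrees = dict(net.degree())
    thr = float(np.percentile(list(degrees.values()), percentile))
    bc = nx.betweenness_centrality(net, normalized=False)
    hubs = [
        {"taxon": v, "degree": d, "betweenness": bc[v]}
        for v, d in degrees.items()
        if d > thr
    ]
    table = pd.DataFrame(hubs, columns=["taxon", "degree", "betweenness"])
    if len(table):
        table = table.sort_values(
            ["degree", "taxon"], ascending=[False, True]
        ).reset_index(drop=True)
    return HubReport(threshold=thr, percentile=percentile, table=table)
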