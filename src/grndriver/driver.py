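"""Centrality fusion and immune driver-gene selection.

The prioritisation works on a directed gene regulatory network:

1. five centrality indices per node — degree (in + out), betweenness on
   the directed graph, eigenvector and closeness on the undirected
   projection, PageRank (damping 0.85);
2. per index, genes are ranked descending (largest centrality = rank 1,
   ties averaged) and converted to rank ratios r_i = rank / n in (0, 1];
3. the N ratios are fused by the order-statistics Q statistic — the
   probability that N iid Uniform(0, 1) order statistics jointly fall
   below the sorted observed ratios.  A gene that ranks near the top on
   every index gets a very small Q, so small Q = consistently central;
4. genes with a top-fraction Q are intersected with an immune gene list
   to form the candidate driver set.

The Q recursion is evaluated in the scaled form W_k = k! * V_k,
W_k = sum_{j=1..k} (-1)^(j-1) C(k, j) W_{k-j} r_{N-k+1}^j with W_0 = 1
and Q = W_N, which is algebraically identical to the factorial form but
free of overflow for any N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

CENTRALITY_INDICES = ("degree", "betweenness", "eigenvector", "pagerank", "closeness")


@dataclass(frozen=True)
class CentralityProfile:
    """Per-gene rank ratios over the N centrality indices."""

    gene: str
    r: tuple[float, ...]
    index_names: tuple[str, ...] = CENTRALITY_INDICES

    def __post_init__(self) -> None:
        if len(self.r) != len(self.index_names) or not self.r:
            raise ValueError("rank-ratio vector must match index_names and be non-empty")
        if any(not 0 < ri <= 1 for ri in self.r):
            raise ValueError("rank ratios must lie in (0, 1]")


@dataclass(frozen=True)
class QResult:
    gene: str
    q: float
    v_trace: tuple[float, ...] | None = None  # W_0..W_N (scaled recursion values)


@dataclass(frozen=True)
class DriverGeneSet:
    genes: tuple[str, ...]
    q_cutoff: float
    top_fraction: float
    immune_list_size: int


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def _eigenvector_undirected(g_und: nx.Graph) -> dict[str, float]:
    """Leading eigenvector of the undirected adjacency (dense, symmetric),
    sign-fixed non-negative and L2-normalised."""
    nodes = list(g_und.nodes)
    a = nx.to_numpy_array(g_und, nodelist=nodes, weight=None)
    vals, vecs = np.linalg.eigh(a)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # numerical negatives on off-component nodes
    v = v / np.linalg.norm(v)
    return dict(zip(nodes, v))


def compute_centralities(g: nx.DiGraph) -> pd.DataFrame:
    """Five centrality indices per node (columns in a fixed order).

    Degree and betweenness (normalised by (n-1)(n-2)) and PageRank
    (damping 0.85, converged well below 1e-9) use the directed graph;
    eigenvector and closeness (component-scaled) use the undirected
    projection, where directed GRNs are otherwise dominated by
    unreachable pairs.  Edge weights are ignored.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network must have at least 2 nodes")
    und = g.to_undirected()
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    pagerank = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=10_000, weight=None)
    eigenvector = _eigenvector_undirected(und)
    closeness = nx.closeness_centrality(und)
    nodes = list(g.nodes)
    return pd.DataFrame(
        {
            "degree": [float(degree[v]) for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "eigenvector": [eigenvector[v] for v in nodes],
            "pagerank": [pagerank[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def rank_ratios(centralities: pd.DataFrame) -> pd.DataFrame:
    """Rank ratios per index: descending ranks (ties averaged) / n genes."""
    if centralities.isna().any().any():
        raise ValueError("NaN centrality values")
    n = len(centralities)
    return centralities.rank(ascending=False, method="average") / n


# ---------------------------------------------------------------------------
# Q statistic
# ---------------------------------------------------------------------------


def q_statistic(r, return_trace: bool = False):
    """Order-statistics fusion of N rank ratios into Q in (0, 1].

    Q equals the probability that the order statistics of N iid
    Uniform(0, 1) draws jointly fall below the sorted ratios:
    P(U_(1) <= r_(1), ..., U_(N) <= r_(N)).  Invariant to the input
    order and monotone non-decreasing in each r_i.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("r must be a non-empty 1-D vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("all rank ratios must lie in (0, 1]")
    rs = np.sort(r)  # ascending: rs[0] = r_(1)
    n = rs.size
    w = [1.0]  # W_0
    for k in range(1, n + 1):
        x = rs[n - k]  # r_{N-k+1}
        acc = 0.0
        for j in range(1, k + 1):
            acc += (-1) ** (j - 1) * math.comb(k, j) * w[k - j] * x**j
        w.append(acc)
    q = float(w[n])
    if return_trace:
        return q, tuple(w)
    return q


def fuse_and_rank(ratios: pd.DataFrame) -> pd.DataFrame:
    """One Q per gene from its rank-ratio row, sorted ascending by Q.

    Ties are broken by gene id so the output order is reproducible.
    Returns the ratio columns alongside ``q``.
    """
    if ratios.isna().any().any():
        raise ValueError("NaN rank ratios")
    q = ratios.apply(lambda row: q_statistic(row.to_numpy()), axis=1)
    out = ratios.copy()
    out.insert(0, "q", q)
    # two-key sort: ascending Q, gene id breaks ties
    return out.iloc[np.lexsort((out.index.astype(str), out["q"].to_numpy()))]


def select_drivers(
    q_table: pd.DataFrame,
    immune_genes: list[str],
    top_fraction: float = 0.05,
    scope: str = "all_nodes",
) -> DriverGeneSet:
    """Intersect the top-fraction smallest-Q genes with the immune list.

    With ``scope='all_nodes'`` the Q cutoff is the ceil(top_fraction * n)-th
    smallest Q over all network genes, then intersected with the immune
    list; ``scope='immune_only'`` computes the cutoff over immune genes
    only.  Genes tied at the cutoff are included.  An empty intersection
    is a valid (empty) result.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    if not immune_genes:
        raise ValueError("immune gene list must be non-empty")
    if scope not in {"all_nodes", "immune_only"}:
        raise ValueError("scope must be 'all_nodes' or 'immune_only'")
    immune = set(immune_genes)
    q = q_table["q"]
    pool = q if scope == "all_nodes" else q[q.index.isin(immune)]
    if pool.empty:
        return DriverGeneSet((), float("nan"), top_fraction, len(immune))
    m = math.ceil(top_fraction * len(pool))
    cutoff = float(np.sort(pool.to_numpy())[m - 1])
    selected = sorted(g for g in q.index[(q <= cutoff)] if g in immune)
    return DriverGeneSet(tuple(selected), cutoff, top_fraction, len(immune))
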