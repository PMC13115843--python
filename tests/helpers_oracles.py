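"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle computes the same quantity as the library by a different
route (enumeration, power iteration, dense linear algebra, Monte-Carlo
sampling) so that agreement is evidence of correctness rather than of
shared code.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def mc_joint_order_stat_prob(r, n_draws: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo estimate (and its standard error) of
    P(U_(1) <= r_(1), ..., U_(N) <= r_(N)) for iid Uniform(0, 1)."""
    r = np.sort(np.asarray(r, dtype=float))
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(size=(n_draws, r.size)), axis=1)
    hit = np.all(u <= r, axis=1)
    est = hit.mean()
    se = max(hit.std(ddof=1) / np.sqrt(n_draws), 1.0 / n_draws)
    return float(est), float(se)


def brute_betweenness(g: nx.DiGraph) -> dict:
    """Directed betweenness by explicit shortest-path enumeration,
    endpoints excluded, normalised by (n-1)(n-2)."""
    nodes = list(g.nodes)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in nodes:
                if v in (s, t):
                    continue
                bc[v] += sum(v in p for p in paths) / len(paths)
    scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: bc[v] * scale for v in nodes}


def brute_pagerank(g: nx.DiGraph, damping: float = 0.85) -> dict:
    """PageRank by dense linear solve; dangling nodes link uniformly."""
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u in nodes:
        succ = list(g.successors(u))
        if succ:
            for v in succ:
                a[idx[u], idx[v]] = 1.0 / len(succ)
        else:
            a[idx[u], :] = 1.0 / n
    p = np.linalg.solve(np.eye(n) - damping * a.T, np.full(n, (1 - damping) / n))
    p = p / p.sum()
    return dict(zip(nodes, p))


def brute_eigenvector_undirected(g: nx.DiGraph, iters: int = 10_000) -> dict:
    """Eigenvector centrality of the undirected projection by power
    iteration from a uniform start, L2-normalised."""
    und = g.to_undirected()
    nodes = list(und.nodes)
    a = nx.to_numpy_array(und, nodelist=nodes, weight=None)
    v = np.ones(len(nodes))
    for _ in range(iters):
        nv = a @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            break
        nv = nv / norm
        if np.linalg.norm(nv - v) < 1e-14:
            v = nv
            break
        v = nv
    return dict(zip(nodes, np.abs(v)))


def brute_closeness_undirected(g: nx.DiGraph) -> dict:
    """Component-scaled closeness of the undirected projection:
    ((nc-1)/sum d) * ((nc-1)/(n-1)) within each connected component."""
    und = g.to_undirected()
    n = und.number_of_nodes()
    out = {}
    for v in und.nodes:
        dist = nx.single_source_shortest_path_length(und, v)
        nc = len(dist)
        total = sum(dist.values())
        if nc <= 1 or total == 0:
            out[v] = 0.0
        else:
            out[v] = ((nc - 1) / total) * ((nc - 1) / (n - 1))
    return out


def random_connected_digraph(rng: np.random.Generator, max_nodes: int = 20) -> nx.DiGraph:
    """Random directed graph whose undirected projection is connected
    and whose leading adjacency eigenvalue is simple (no eigenvector
    degeneracy for the oracles to disagree on)."""
    while True:
        n = int(rng.integers(5, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.4))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
        if g.number_of_edges() == 0 or not nx.is_connected(g.to_undirected()):
            continue
        a = nx.to_numpy_array(g.to_undirected(), weight=None)
        ev = np.sort(np.linalg.eigvalsh(a))
        if ev[-1] - ev[-2] < 1e-6:
            continue
        return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


def brute_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the step-up definition, evaluated literally."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def brute_ssgsea_score(values, in_set, alpha: float) -> float:
    """ssGSEA running sum for one sample, evaluated position by position.

    ``values``: expression vector; ``in_set``: boolean membership mask in
    the same gene order.  Uses the same convention as the library
    (descending rank, weight (G - position)^alpha) but computed by an
    explicit loop.
    """
    values = np.asarray(values, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    g = values.size
    order = np.argsort(-values, kind="stable")
    w_total = sum(
        (g - pos) ** alpha for pos, i in enumerate(order) if in_set[i]
    )
    n_out = int((~in_set).sum())
    score = 0.0
    p_in = 0.0
    p_out = 0.0
    for pos, i in enumerate(order):
        if in_set[i]:
            p_in += (g - pos) ** alpha / w_total
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score
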