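"""Patient stratification: consensus clustering, k selection, IGP.

Consensus clustering follows the Monti resampling scheme: repeatedly
subsample the cohort, cluster each subsample (agglomerative, average
linkage on 1 - Pearson correlation), and record for each sample pair the
fraction of co-sampled runs in which the pair co-clustered.  The number
of clusters is chosen from the consensus-CDF area curve: the largest k
whose relative area gain over k-1 still exceeds a threshold.  Cluster
reproducibility in an independent cohort is measured by the in-group
proportion (IGP): classify validation samples to the nearest reference
centroid, then ask how often a sample's nearest validation neighbour
shares its assigned cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .scoring import ssgsea

logger = logging.getLogger(__name__)


@dataclass
class ConsensusClusteringResult:
    k_range: tuple[int, ...]
    consensus: dict[int, pd.DataFrame]  # k -> samples x samples in [0, 1]
    labels: dict[int, pd.Series]  # k -> cluster label per sample
    cdf_area: dict[int, float] = field(default_factory=dict)
    delta_area: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None


@dataclass
class IgpResult:
    igp: dict[str, float]  # cluster -> IGP (NaN when < 2 samples assigned)
    n_validation_samples: int
    p_values: dict[str, float] | None = None
    assignments: pd.Series | None = None


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns, clipped to [0, 2]."""
    xc = x - x.mean(axis=0, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=0, keepdims=True))
    norm[norm == 0] = 1.0  # constant profiles: zero-corr convention
    c = (xc / norm).T @ (xc / norm)
    d = 1.0 - np.clip(c, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _agglomerative(dist: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage agglomerative clustering on a precomputed distance
    matrix; labels renumbered 1..k by order of first appearance."""
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # canonical label order for reproducible artifacts
    order = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in order:
            order[lab] = len(order) + 1
        out[i] = order[lab]
    return out


def consensus_cluster(
    expr: pd.DataFrame,
    k_range=range(2, 7),
    n_resamples: int = 500,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusClusteringResult:
    """Monti consensus clustering of samples (columns of ``expr``).

    Per resample a fraction of samples is drawn without replacement and
    clustered agglomeratively (average linkage, 1 - Pearson distance);
    consensus(i, j) is the co-clustering count over the co-sampling
    count.  Final labels per k come from average-linkage clustering of
    1 - consensus.  Fully deterministic given the seed.
    """
    k_range = tuple(k_range)
    if len(expr.index) < 2:
        raise ValueError("need at least 2 genes to cluster on")
    n = expr.shape[1]
    if n < 3 * max(k_range):
        raise ValueError("need at least 3 samples per candidate cluster")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = max(2, int(np.floor(subsample_fraction * n)))
    dist = _correlation_distance(expr.to_numpy(dtype=float))
    samples = list(expr.columns)

    consensus: dict[int, pd.DataFrame] = {}
    labels: dict[int, pd.Series] = {}
    for k in k_range:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = _agglomerative(dist[np.ix_(idx, idx)], k)
            co_sample[np.ix_(idx, idx)] += 1.0
            same = sub[:, None] == sub[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        off = ~np.eye(n, dtype=bool)
        if np.any(co_sample[off] == 0):
            raise ValueError(
                "some sample pairs were never co-sampled; increase n_resamples"
            )
        with np.errstate(invalid="ignore"):
            cons = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus[k] = pd.DataFrame(cons, index=samples, columns=samples)
        lab = _agglomerative(1.0 - cons, k)
        labels[k] = pd.Series([f"C{v}" for v in lab], index=samples, name="cluster")
    return ConsensusClusteringResult(k_range=k_range, consensus=consensus, labels=labels)


def _cdf_area(values: np.ndarray) -> float:
    """Area under the empirical CDF of consensus values on [0, 1]."""
    xs = np.sort(values)
    m = xs.size
    area = 0.0
    for i in range(1, m):
        area += (xs[i] - xs[i - 1]) * i / m
    area += (1.0 - xs[-1]) * 1.0
    return float(area)


def select_k_cdf_delta(
    res: ConsensusClusteringResult, delta_threshold: float = 0.05
) -> int:
    """Choose k by the CDF delta-area rule and record it on the result.

    A(k) is the area under the CDF of the upper-triangle consensus
    values; Delta(k) is A(k_min) for the smallest k and the relative gain
    (A(k) - A(k-1)) / A(k-1) afterwards.  Chosen k is the largest k with
    Delta(k) >= threshold, falling back to the smallest k when no k
    qualifies (a single-cluster degenerate cohort).
    """
    if len(res.k_range) < 2:
        raise ValueError("need at least 2 candidate k values")
    ks = sorted(res.k_range)
    areas = {}
    for k in ks:
        c = res.consensus[k].to_numpy()
        iu = np.triu_indices_from(c, k=1)
        areas[k] = _cdf_area(c[iu])
    deltas = {}
    for i, k in enumerate(ks):
        if i == 0:
            deltas[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else areas[k] - prev
    qualifying = [k for k in ks if deltas[k] >= delta_threshold]
    chosen = max(qualifying) if qualifying else ks[0]
    res.cdf_area, res.delta_area, res.chosen_k = areas, deltas, chosen
    return chosen


# ---------------------------------------------------------------------------
# In-group proportion (IGP)
# ---------------------------------------------------------------------------


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def igp(
    reference_expr: pd.DataFrame,
    reference_labels: pd.Series,
    validation_expr: pd.DataFrame,
    n_permutations: int = 0,
    seed: int = 0,
) -> IgpResult:
    """In-group proportion of reference clusters in a validation cohort.

    Genes are intersected across cohorts (logged) and z-scored per cohort
    to remove cohort-level scale.  Validation samples are assigned to the
    nearest reference-cluster centroid by Pearson correlation; IGP(g) is
    the fraction of samples assigned to g whose nearest validation
    neighbour (correlation, excluding self) is also assigned to g.
    Clusters with fewer than 2 assigned samples get a missing IGP.  With
    ``n_permutations`` a null IGP is computed per cluster by permuting
    centroid gene labels, giving a permutation p-value.
    """
    shared = [g for g in reference_expr.index if g in set(validation_expr.index)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between cohorts")
    if len(shared) < len(reference_expr.index):
        logger.info(
            "IGP: %d/%d genes shared across cohorts", len(shared), len(reference_expr.index)
        )
    labels = pd.Series(reference_labels).reindex(reference_expr.columns)
    clusters = sorted(labels.dropna().unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 reference clusters")

    ref = _zscore_rows(reference_expr.loc[shared].to_numpy(dtype=float))
    val = _zscore_rows(validation_expr.loc[shared].to_numpy(dtype=float))
    centroids = np.column_stack(
        [ref[:, (labels == c).to_numpy()].mean(axis=1) for c in clusters]
    )

    def _colcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ac = a - a.mean(axis=0, keepdims=True)
        bc = b - b.mean(axis=0, keepdims=True)
        an = np.sqrt((ac**2).sum(axis=0, keepdims=True))
        bn = np.sqrt((bc**2).sum(axis=0, keepdims=True))
        an[an == 0] = 1.0
        bn[bn == 0] = 1.0
        return (ac / an).T @ (bc / bn)

    def _igp_values(cent: np.ndarray) -> dict[str, float]:
        assign = np.argmax(_colcorr(val, cent), axis=1)
        vv = _colcorr(val, val)
        np.fill_diagonal(vv, -np.inf)
        nearest = np.argmax(vv, axis=1)
        out = {}
        for ci, c in enumerate(clusters):
            members = np.flatnonzero(assign == ci)
            if members.size < 2:
                out[c] = float("nan")
            else:
                out[c] = float(np.mean(assign[nearest[members]] == ci))
        return out

    values = _igp_values(centroids)
    assign = np.argmax(_colcorr(val, centroids), axis=1)
    assignments = pd.Series(
        [clusters[i] for i in assign], index=validation_expr.columns, name="cluster"
    )

    p_values = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = {c: 0 for c in clusters}
        valid = {c: 0 for c in clusters}
        for _ in range(n_permutations):
            perm = rng.permutation(centroids.shape[0])
            null = _igp_values(centroids[perm])
            for c in clusters:
                if not np.isnan(null[c]) and not np.isnan(values[c]):
                    valid[c] += 1
                    if null[c] >= values[c]:
                        exceed[c] += 1
        p_values = {
            c: (exceed[c] + 1) / (valid[c] + 1) if valid[c] else float("nan")
            for c in clusters
        }
    return IgpResult(
        igp=values,
        n_validation_samples=validation_expr.shape[1],
        p_values=p_values,
        assignments=assignments,
    )


def cluster_signature_scores(
    expr: pd.DataFrame,
    cluster_signatures: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA score of each cluster signature per sample (clusters x samples)."""
    for name, sig in cluster_signatures.items():
        if not set(sig) & set(expr.index):
            raise ValueError(f"signature {name!r} empty after intersection")
    return ssgsea(expr, cluster_signatures, alpha=alpha, normalize=normalize)
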