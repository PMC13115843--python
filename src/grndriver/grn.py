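"""Regulons, gene regulatory networks and rank-based regulon activity.

A *regulon* is a transcription factor together with its target genes.
Regulons are either ingested from a TSV edge table or inferred from an
expression matrix with a Spearman-correlation screen (keep the
``top_n_targets`` strongest correlates per TF above ``min_abs_rho``, drop
modules below ``min_module_size``).  Per-cell regulon activity is the
AUCell-style recovery AUC: the area under the curve counting regulon genes
within the top ``auc_threshold`` fraction of the cell's expression
ranking, normalised to [0, 1] by the maximum achievable area.  The score
depends only on ranks, so it is invariant to any strictly monotone
transform of a cell's expression values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scoring import bh_fdr, kruskal_wallis, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Regulon:
    """A TF with its ordered target set and optional per-target weights."""

    tf: str
    targets: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"regulon {self.tf}: targets must be non-empty")
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf}: self-loop not allowed")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.tf}: duplicate targets")
        if self.weights is not None:
            if len(self.weights) != len(self.targets):
                raise ValueError(f"regulon {self.tf}: weights misaligned with targets")
            if any(w < 0 for w in self.weights):
                raise ValueError(f"regulon {self.tf}: weights must be non-negative")

    def __len__(self) -> int:
        return len(self.targets)


RegulonSet = list[Regulon]


# ---------------------------------------------------------------------------
# Ingestion and inference
# ---------------------------------------------------------------------------


def read_regulon_table(path) -> RegulonSet:
    """Read a TSV of (tf, target[, weight]) rows into one regulon per TF.

    Duplicate (tf, target) rows collapse to a single edge keeping the
    maximum weight; self-loop rows are rejected with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    missing = {"tf", "target"} - set(df.columns)
    if missing:
        raise ValueError(f"regulon table missing required columns: {sorted(missing)}")
    loops = df.index[df["tf"] == df["target"]]
    if len(loops):
        raise ValueError(
            f"self-loop rows in regulon table (data row {int(loops[0]) + 1}: "
            f"{df.loc[loops[0], 'tf']})"
        )
    has_weight = "weight" in df.columns
    if has_weight:
        df = df.groupby(["tf", "target"], as_index=False, sort=False)["weight"].max()
    else:
        df = df.drop_duplicates(subset=["tf", "target"])
    regulons = []
    for tf, block in df.groupby("tf", sort=True):
        regulons.append(
            Regulon(
                tf=tf,
                targets=tuple(block["target"]),
                weights=tuple(block["weight"]) if has_weight else None,
            )
        )
    return regulons


def write_regulon_table(regulons: RegulonSet, path) -> None:
    rows = []
    for r in regulons:
        w = r.weights if r.weights is not None else [1.0] * len(r.targets)
        rows.extend((r.tf, t, wi) for t, wi in zip(r.targets, w))
    pd.DataFrame(rows, columns=["tf", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def infer_grn_correlation(
    expr: pd.DataFrame,
    tf_list: list[str],
    top_n_targets: int = 50,
    min_module_size: int = 21,
    min_abs_rho: float = 0.2,
) -> RegulonSet:
    """Spearman-correlation regulon screen.

    For each TF, rank all other genes by \\|rho\\| against the TF across
    cells, keep the ``top_n_targets`` with \\|rho\\| >= ``min_abs_rho`` and
    discard modules smaller than ``min_module_size``.  A
    constant-expression TF has undefined correlations; its regulon is
    skipped with a warning rather than failing the run.
    """
    missing = set(tf_list) - set(expr.index)
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {sorted(missing)}")
    if expr.shape[1] < 30:
        raise ValueError("need at least 30 observations for correlation inference")

    x = expr.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, x)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    gene_index = {g: i for i, g in enumerate(expr.index)}
    genes = np.asarray(expr.index)

    regulons: RegulonSet = []
    for tf in tf_list:
        i = gene_index[tf]
        if norms[i] == 0:
            logger.warning("TF %s has constant expression; regulon skipped", tf)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = ranks @ ranks[i] / (norms * norms[i])
        rho[i] = 0.0  # never a self-target
        rho = np.nan_to_num(rho)  # constant genes contribute nothing
        keep = np.flatnonzero(np.abs(rho) >= min_abs_rho)
        if keep.size == 0:
            continue
        order = keep[np.argsort(-np.abs(rho[keep]), kind="stable")][:top_n_targets]
        if order.size < min_module_size:
            continue
        regulons.append(
            Regulon(
                tf=tf,
                targets=tuple(genes[order]),
                weights=tuple(np.abs(rho[order])),
            )
        )
    return regulons


def regulons_to_network(regulons: RegulonSet) -> nx.DiGraph:
    """Union of all TF -> target edges as a directed graph."""
    if not regulons:
        raise ValueError("empty regulon set")
    g = nx.DiGraph()
    for r in regulons:
        w = r.weights if r.weights is not None else [1.0] * len(r.targets)
        for t, wi in zip(r.targets, w):
            if g.has_edge(r.tf, t):
                g[r.tf][t]["weight"] = max(g[r.tf][t]["weight"], wi)
            else:
                g.add_edge(r.tf, t, weight=wi)
    return g


# ---------------------------------------------------------------------------
# AUCell-style activity
# ---------------------------------------------------------------------------


def aucell_activity(
    expr: pd.DataFrame,
    regulons: RegulonSet,
    auc_threshold: float = 0.05,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Recovery-AUC regulon activity per cell, values in [0, 1].

    Per cell, genes are ranked by descending expression with ties broken
    by a deterministic seeded permutation; the recovery curve counts
    regulon genes within the top k ranks for k = 1..ceil(threshold * G),
    and the activity is its area divided by the maximum achievable area.
    Regulon genes absent from the matrix are dropped with a logged count;
    a regulon with no gene present is an error.
    """
    if not 0 < auc_threshold < 1:
        raise ValueError("auc_threshold must lie in (0, 1)")
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_cells = expr.shape
    k_max = math.ceil(auc_threshold * n_genes)

    masks = []
    for r in regulons:
        present = [gene_pos[t] for t in r.targets if t in gene_pos]
        dropped = len(r.targets) - len(present)
        if dropped:
            logger.warning("regulon %s: %d target(s) absent from matrix", r.tf, dropped)
        if not present:
            raise ValueError(f"regulon {r.tf}: no genes present in the matrix")
        masks.append(np.asarray(present))

    rng = np.random.default_rng(tie_seed)
    x = expr.to_numpy(dtype=float)
    act = np.empty((len(regulons), n_cells))
    # per-cell rank position of every gene (0 = top), random tie-break
    for c in range(n_cells):
        perm = rng.permutation(n_genes)
        order = perm[np.argsort(-x[perm, c], kind="stable")]
        pos = np.empty(n_genes, dtype=int)
        pos[order] = np.arange(n_genes)
        for j, mask in enumerate(masks):
            p = pos[mask]
            p = p[p < k_max]
            area = float(np.sum(k_max - p))
            m = min(len(mask), k_max)
            max_area = m * k_max - m * (m - 1) // 2
            act[j, c] = area / max_area
    return pd.DataFrame(act, index=[r.tf for r in regulons], columns=expr.columns)


def differential_regulon_activity(
    activity: pd.DataFrame, groups: pd.Series | dict
) -> pd.DataFrame:
    """Per-regulon rank test of activity between cell groups.

    Two groups use the Wilcoxon rank-sum test, three or more the
    Kruskal-Wallis test; p-values are BH-corrected across regulons.
    ``direction`` is the label of the group with the highest mean
    activity.
    """
    groups = pd.Series(groups).reindex(activity.columns)
    if groups.isna().any():
        raise ValueError("every cell must have a group label")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    split = {g: activity.columns[groups == g] for g in levels}
    if any(len(c) < 2 for c in split.values()):
        raise ValueError("every group needs at least 2 cells")

    rows = []
    for reg in activity.index:
        vals = [activity.loc[reg, cols].to_numpy() for g, cols in split.items()]
        if len(levels) == 2:
            stat, p = wilcoxon_rank_sum(vals[0], vals[1])
        else:
            stat, p = kruskal_wallis(vals)
        means = [v.mean() for v in vals]
        rows.append((reg, stat, p, levels[int(np.argmax(means))]))
    out = pd.DataFrame(rows, columns=["regulon", "statistic", "p", "direction"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out[["regulon", "statistic", "p", "fdr", "direction"]]
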