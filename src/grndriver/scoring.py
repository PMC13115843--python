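"""Statistical layer: ssGSEA, rank tests, FDR, survival, TMB.

Thin, explicit wrappers around scipy / statsmodels / lifelines for the
standard tests, plus a rank-weighted single-sample gene set enrichment
(ssGSEA) implementation.  Every function takes and returns plain pandas /
numpy objects so the layers above stay decoupled from the statistical
backends.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import NONSYNONYMOUS_CLASSES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def ssgsea(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample gene set enrichment scores (gene sets x samples).

    Per sample, genes are ranked by descending expression; walking down
    the ranking, the running difference between the weighted in-set ECDF
    (in-set steps weighted by rank^alpha, where the top gene carries the
    largest rank weight G) and the uniform out-of-set ECDF is summed over
    all positions.  Scores depend only on ranks, hence are invariant to
    strictly monotone per-sample transforms.  With ``normalize`` the whole
    matrix is divided by its global score range.
    """
    genes = list(expr.index)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    set_masks = {}
    for name, members in gene_sets.items():
        idx = sorted({gene_pos[g] for g in members if g in gene_pos})
        if not idx:
            raise ValueError(f"gene set {name!r}: no members present in the matrix")
        if len(idx) >= n_genes:
            raise ValueError(f"gene set {name!r} covers every gene (out-set empty)")
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        set_masks[name] = mask

    x = expr.to_numpy(dtype=float)
    # descending order per sample; stable sort keeps tie handling deterministic
    order = np.argsort(-x, axis=0, kind="stable")
    # rank weight: position i (0-based from top) carries weight (G - i)^alpha
    w = (n_genes - np.arange(n_genes)) ** alpha

    scores = np.empty((len(set_masks), expr.shape[1]))
    for c in range(expr.shape[1]):
        ord_c = order[:, c]
        for j, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[ord_c]
            w_in = np.where(in_set, w, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            out = (~in_set).astype(float)
            p_out = np.cumsum(out) / out.sum()
            scores[j, c] = float(np.sum(p_in - p_out))
    out_df = pd.DataFrame(scores, index=list(set_masks), columns=expr.columns)
    if normalize:
        rng_ = float(out_df.to_numpy().max() - out_df.to_numpy().min())
        if rng_ > 0:
            out_df = out_df / rng_
    return out_df


def lineage_infiltration(
    expr_bulk: pd.DataFrame,
    lineage_marker_sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA infiltration scores of cell-lineage marker sets (lineages x samples)."""
    for name, members in lineage_marker_sets.items():
        if not set(members) & set(expr_bulk.index):
            raise ValueError(f"marker set {name!r} absent from the matrix")
    return ssgsea(expr_bulk, lineage_marker_sets, alpha=alpha, normalize=normalize)


def driver_infiltration_correlation(
    driver_expr: pd.DataFrame, lineage_scores: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of each driver gene with each lineage score.

    Returns one row per (gene, lineage) with rho, p and BH FDR across all
    pairs; constant vectors yield missing rho/p (excluded from the FDR).
    """
    common = [s for s in driver_expr.columns if s in lineage_scores.columns]
    if not common:
        raise ValueError("no shared samples")
    rows = []
    for gene in driver_expr.index:
        gx = driver_expr.loc[gene, common].to_numpy(dtype=float)
        for lin in lineage_scores.index:
            ly = lineage_scores.loc[lin, common].to_numpy(dtype=float)
            if np.ptp(gx) == 0 or np.ptp(ly) == 0:
                rows.append((gene, lin, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(gx, ly)
            rows.append((gene, lin, rho, p))
    out = pd.DataFrame(rows, columns=["gene", "lineage", "rho", "p"])
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Rank tests, FDR, survival
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p for small tie-free samples, otherwise the tie- and
    continuity-corrected normal approximation (scipy's auto policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with a chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use wilcoxon_rank_sum for 2)")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_rank(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square across k groups (k-1 df) over pooled event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    if events.sum() < 1:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def spearman(x, y) -> tuple[float, float]:
    rho, p = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Mutation burden, differential expression, response association
# ---------------------------------------------------------------------------


def tmb(
    mutations: pd.DataFrame,
    samples: list[str] | None = None,
    nonsynonymous: frozenset[str] = NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Per-sample nonsynonymous variant count (TMB) and mutated-gene count.

    ``samples`` fixes the output rows (zero counts for samples without
    mutations); by default the samples present in the table are used.
    """
    required = {"sample", "gene", "variant_classification"}
    missing = required - set(mutations.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    ns = mutations[mutations["variant_classification"].isin(nonsynonymous)]
    counts = ns.groupby("sample").size()
    gene_counts = ns.groupby("sample")["gene"].nunique()
    idx = samples if samples is not None else sorted(mutations["sample"].unique())
    return pd.DataFrame(
        {
            "tmb": counts.reindex(idx, fill_value=0).astype(int),
            "mutated_genes": gene_counts.reindex(idx, fill_value=0).astype(int),
        },
        index=pd.Index(idx, name="sample"),
    )


def differential_expression(expr: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Per-gene Wilcoxon test between two sample groups with BH FDR.

    log2FC is the difference of group means on the log2(x + 1) scale
    (first group label in sorted order minus the second).
    """
    labels = pd.Series(labels).reindex(expr.columns)
    levels = sorted(labels.dropna().unique())
    if len(levels) != 2:
        raise ValueError("differential_expression requires exactly 2 groups")
    a = expr.columns[labels == levels[0]]
    b = expr.columns[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    la = np.log2(expr[a].to_numpy(dtype=float) + 1)
    lb = np.log2(expr[b].to_numpy(dtype=float) + 1)
    rows = []
    for i, gene in enumerate(expr.index):
        if np.ptp(np.concatenate([la[i], lb[i]])) == 0:
            p = 1.0
        else:
            _, p = wilcoxon_rank_sum(la[i], lb[i])
        rows.append((gene, float(la[i].mean() - lb[i].mean()), p))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out


RESPONDER_LABELS = frozenset({"CR", "PR"})
NONRESPONDER_LABELS = frozenset({"SD", "PD"})


def response_association(
    scores: pd.Series, response: pd.Series, dichotomize: bool = True
) -> dict:
    """Association of a per-sample score with immunotherapy response.

    With ``dichotomize`` (default) responders (CR/PR) are compared to
    non-responders (SD/PD) by Wilcoxon; otherwise all response categories
    are compared by Kruskal-Wallis.  ``direction`` is positive when
    responders score higher.
    """
    scores = pd.Series(scores)
    response = pd.Series(response).reindex(scores.index)
    ok = response.notna() & (response != "NA")
    scores, response = scores[ok], response[ok]
    if dichotomize:
        is_resp = response.isin(RESPONDER_LABELS)
        if is_resp.all() or (~is_resp).all():
            raise ValueError("need both responders and non-responders")
        r, n = scores[is_resp], scores[~is_resp]
        stat, p = wilcoxon_rank_sum(r, n)
        return {
            "test": "wilcoxon",
            "statistic": stat,
            "p": p,
            "direction": float(np.sign(r.mean() - n.mean())),
        }
    levels = sorted(response.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 response categories")
    groups = [scores[response == lv].to_numpy() for lv in levels]
    if len(levels) == 2:
        stat, p = wilcoxon_rank_sum(groups[0], groups[1])
        test = "wilcoxon"
    else:
        stat, p = kruskal_wallis(groups)
        test = "kruskal-wallis"
    best = levels[int(np.argmax([g.mean() for g in groups]))]
    return {"test": test, "statistic": stat, "p": p, "direction": best}
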