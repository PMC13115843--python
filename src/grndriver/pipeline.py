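"""End-to-end orchestration of the driver-gene / stratification pipeline.

Stage order mirrors the analysis: regulon ingest or inference ->
per-cell regulon activity -> network construction -> centralities ->
Q-statistic fusion -> immune driver selection -> consensus clustering of
the bulk cohort on driver genes -> k selection -> cluster signature
scores -> clinical statistics.  Every artifact is written under the run
directory together with a manifest recording input checksums, parameters
and the seed; a rerun with an identical manifest reproduces all outputs
bitwise.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import driver as driver_mod
from . import grn as grn_mod
from . import scoring
from .io import (
    PipelineConfig,
    read_clinical,
    read_expression,
    read_gene_list,
    read_mutations,
    sha256_of,
    write_gene_list,
    write_table,
    write_yaml,
)

logger = logging.getLogger(__name__)

STAGES = (
    "regulons",
    "activity",
    "network",
    "centralities",
    "q_table",
    "drivers",
    "clustering",
    "signature_scores",
    "statistics",
)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _require(cfg_value, stage: str, what: str):
    if cfg_value is None:
        raise PipelineError(stage, "missing_input", f"{what} not configured")
    p = Path(cfg_value)
    if not p.exists():
        raise PipelineError(stage, "missing_input", f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # output_dir is where the run lands, not part of what it computes;
    # leaving it out makes "equal manifests => equal outputs" hold exactly
    params = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    manifest: dict = {
        "parameters": params,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }

    def _record_input(name: str, path: Path) -> None:
        manifest["inputs"][name] = {"path": str(path), "sha256": sha256_of(path)}

    def _record_stage(stage: str, *files: Path) -> None:
        manifest["stages"][stage] = [f.name for f in files]

    # --- inputs -----------------------------------------------------------
    expr_path = _require(config.expression, "regulons", "single-cell expression")
    expr = read_expression(expr_path)
    _record_input("expression", expr_path)

    # --- stage 1: regulons ------------------------------------------------
    if config.regulons is not None:
        reg_path = _require(config.regulons, "regulons", "regulon table")
        regulons = grn_mod.read_regulon_table(reg_path)
        _record_input("regulons", reg_path)
    else:
        tf_path = _require(config.tf_list, "regulons", "TF list")
        tf_list = read_gene_list(tf_path)
        _record_input("tf_list", tf_path)
        regulons = grn_mod.infer_grn_correlation(
            expr,
            tf_list,
            top_n_targets=config.top_n_targets,
            min_module_size=config.min_module_size,
            min_abs_rho=config.min_abs_rho,
        )
    if not regulons:
        raise PipelineError("regulons", "empty_result", "no regulons survived")
    reg_out = out / "regulons.tsv"
    grn_mod.write_regulon_table(regulons, reg_out)
    _record_stage("regulons", reg_out)

    # --- stage 2: regulon activity ---------------------------------------
    activity = grn_mod.aucell_activity(
        expr, regulons, auc_threshold=config.auc_threshold, tie_seed=config.seed
    )
    act_out = out / "activity.tsv"
    write_table(activity, act_out)
    _record_stage("activity", act_out)

    # --- stage 3: network -------------------------------------------------
    network = grn_mod.regulons_to_network(regulons)
    net_out = out / "network_edges.tsv"
    edges = pd.DataFrame(
        [(u, v, d.get("weight", 1.0)) for u, v, d in network.edges(data=True)],
        columns=["tf", "target", "weight"],
    )
    write_table(edges, net_out, index=False)
    _record_stage("network", net_out)

    # --- stage 4: centralities -------------------------------------------
    centralities = driver_mod.compute_centralities(network)
    cent_out = out / "centralities.tsv"
    write_table(centralities, cent_out)
    _record_stage("centralities", cent_out)

    # --- stage 5: Q fusion ------------------------------------------------
    ratios = driver_mod.rank_ratios(centralities)
    q_table = driver_mod.fuse_and_rank(ratios)
    q_out = out / "q_table.tsv"
    write_table(q_table, q_out)
    _record_stage("q_table", q_out)

    # --- stage 6: driver selection ---------------------------------------
    immune_path = _require(config.immune_list, "drivers", "immune gene list")
    immune = read_gene_list(immune_path)
    _record_input("immune_list", immune_path)
    drivers = driver_mod.select_drivers(
        q_table, immune, top_fraction=config.top_fraction, scope=config.driver_scope
    )
    if not drivers.genes:
        logger.warning("driver selection produced an empty set")
    drv_out = out / "drivers.txt"
    write_gene_list(drivers.genes, drv_out)
    drv_meta = out / "drivers_meta.yaml"
    write_yaml(
        {
            "q_cutoff": drivers.q_cutoff,
            "top_fraction": drivers.top_fraction,
            "immune_list_size": drivers.immune_list_size,
            "n_selected": len(drivers.genes),
        },
        drv_meta,
    )
    _record_stage("drivers", drv_out, drv_meta)

    # --- stage 7: consensus clustering of the bulk cohort -----------------
    bulk_path = _require(config.bulk_expression, "clustering", "bulk expression")
    bulk = read_expression(bulk_path)
    _record_input("bulk_expression", bulk_path)
    cluster_genes = [g for g in drivers.genes if g in bulk.index]
    if len(cluster_genes) < 2:
        raise PipelineError(
            "clustering", "too_few_genes", "fewer than 2 driver genes in bulk matrix"
        )
    res = cohort_mod.consensus_cluster(
        bulk.loc[cluster_genes],
        k_range=config.k_range,
        n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction,
        seed=config.seed,
    )
    chosen_k = cohort_mod.select_k_cdf_delta(res, delta_threshold=config.delta_threshold)
    labels = res.labels[chosen_k]
    lab_out = out / "cluster_labels.tsv"
    write_table(labels.rename("cluster").to_frame(), lab_out)
    krep_out = out / "k_selection.tsv"
    write_table(
        pd.DataFrame(
            {
                "k": list(res.cdf_area),
                "cdf_area": list(res.cdf_area.values()),
                "delta_area": [res.delta_area[k] for k in res.cdf_area],
                "chosen": [int(k == chosen_k) for k in res.cdf_area],
            }
        ),
        krep_out,
        index=False,
    )
    cons_files = []
    for k, cons in res.consensus.items():
        f = out / f"consensus_k{k}.tsv"
        write_table(cons, f)
        cons_files.append(f)
    _record_stage("clustering", lab_out, krep_out, *cons_files)

    # --- stage 8: cluster signature scores -------------------------------
    # signature per cluster: driver genes most up-regulated one-vs-rest
    # (mean log2(x+1) difference; robust to arbitrarily small clusters)
    log_bulk = np.log2(bulk.loc[cluster_genes] + 1)
    signatures: dict[str, list[str]] = {}
    per_sig = max(3, len(cluster_genes) // chosen_k)
    for c in sorted(labels.unique()):
        in_cols = labels.index[labels == c]
        out_cols = labels.index[labels != c]
        lfc = log_bulk[in_cols].mean(axis=1) - log_bulk[out_cols].mean(axis=1)
        lfc = lfc.sort_values(ascending=False, kind="stable")
        up = lfc[lfc > 0]
        signatures[c] = list((up if len(up) >= 3 else lfc).index[:per_sig])
    scores = cohort_mod.cluster_signature_scores(bulk, signatures, alpha=config.alpha)
    sco_out = out / "signature_scores.tsv"
    write_table(scores, sco_out)
    sig_out = out / "cluster_signatures.yaml"
    write_yaml(signatures, sig_out)
    _record_stage("signature_scores", sco_out, sig_out)

    # --- stage 9: clinical statistics -------------------------------------
    stats_rows = []
    clinical = None
    if config.clinical is not None:
        clin_path = _require(config.clinical, "statistics", "clinical table")
        clinical = read_clinical(clin_path).set_index("sample")
        _record_input("clinical", clin_path)
        common = [s for s in labels.index if s in clinical.index]
        cl = clinical.loc[common]
        grp = labels.loc[common]
        try:
            chi2, p = scoring.log_rank(cl["time"], cl["event"], grp)
            stats_rows.append(("log_rank_clusters", chi2, p, ""))
        except ValueError as exc:
            raise PipelineError("statistics", "logrank_failed", str(exc)) from exc
        if "response" in cl.columns:
            for c in scores.index:
                sc = scores.loc[c, common]
                try:
                    assoc = scoring.response_association(sc, cl["response"])
                    stats_rows.append(
                        (f"response_{c}", assoc["statistic"], assoc["p"], assoc["direction"])
                    )
                except ValueError:
                    pass
    if config.mutations is not None:
        mut_path = _require(config.mutations, "statistics", "mutation table")
        muts = read_mutations(mut_path)
        _record_input("mutations", mut_path)
        burden = scoring.tmb(muts, samples=list(labels.index))
        write_table(burden, out / "tmb.tsv")
        groups = [
            burden.loc[labels.index[labels == c], "tmb"].to_numpy()
            for c in sorted(labels.unique())
        ]
        if len(groups) >= 3:
            h, p = scoring.kruskal_wallis(groups)
            stats_rows.append(("tmb_kruskal_wallis", h, p, ""))
        elif len(groups) == 2:
            s, p = scoring.wilcoxon_rank_sum(groups[0], groups[1])
            stats_rows.append(("tmb_wilcoxon", s, p, ""))
    stat_out = out / "statistics.tsv"
    write_table(
        pd.DataFrame(stats_rows, columns=["test", "statistic", "p", "direction"]),
        stat_out,
        index=False,
    )
    _record_stage("statistics", stat_out)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
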