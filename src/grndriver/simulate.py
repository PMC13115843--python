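"""Synthetic cohorts with planted regulatory and clinical structure.

Two generators provide every input the pipeline consumes, plus the ground
truth needed to score recovery:

* a multi-lineage single-cell count matrix in which designated hub
  transcription factors drive planted regulons with lineage-dependent
  activity (negative-binomial counts, independent dropout);
* a bulk expression cohort with three planted sample clusters carrying
  disjoint signature gene sets, cluster-dependent exponential survival,
  response labels and per-sample mutation tables.

All randomness flows through one ``numpy.random.Generator`` per call,
seeded explicitly; the same seed reproduces every output bitwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

LINEAGES = ("lymphoid", "myeloid", "tumor")

#: MAF-style variant classifications counted as nonsynonymous for TMB.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

SYNONYMOUS_CLASSES = ("Silent", "3'UTR", "5'UTR", "Intron")


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedRegulon:
    """A planted TF -> targets module with per-lineage activity in [0, 1]."""

    tf: str
    targets: tuple[str, ...]
    activity: dict[str, float]  # lineage -> activity level


@dataclass
class SyntheticSingleCellTruth:
    regulons: list[PlantedRegulon]
    lineage_of_cell: dict[str, str]
    planted_hub_tfs: list[str]

    def to_dict(self) -> dict:
        return {
            "regulons": [
                {"tf": r.tf, "targets": list(r.targets), "activity": dict(r.activity)}
                for r in self.regulons
            ],
            "lineage_of_cell": dict(self.lineage_of_cell),
            "planted_hub_tfs": list(self.planted_hub_tfs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSingleCellTruth":
        return cls(
            regulons=[
                PlantedRegulon(r["tf"], tuple(r["targets"]), dict(r["activity"]))
                for r in d["regulons"]
            ],
            lineage_of_cell=dict(d["lineage_of_cell"]),
            planted_hub_tfs=list(d["planted_hub_tfs"]),
        )

    def planted_edges(self) -> set[tuple[str, str]]:
        return {(r.tf, t) for r in self.regulons for t in r.targets}


@dataclass
class SyntheticCohortTruth:
    cluster_of_sample: dict[str, str]
    signature_genes: dict[str, list[str]]
    hazard_of_cluster: dict[str, float]
    response_prob_of_cluster: dict[str, float]
    mutation_rate_of_cluster: dict[str, float]

    def __post_init__(self) -> None:
        sigs = list(self.signature_genes.values())
        for i in range(len(sigs)):
            for j in range(i + 1, len(sigs)):
                if set(sigs[i]) & set(sigs[j]):
                    raise ValueError("cluster signatures must be pairwise disjoint")
        if any(h <= 0 for h in self.hazard_of_cluster.values()):
            raise ValueError("hazard rates must be positive")
        if any(not 0 <= p <= 1 for p in self.response_prob_of_cluster.values()):
            raise ValueError("response probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortTruth":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


@dataclass
class CohortSpec:
    """Parameters of the planted bulk cohort (three clusters by default).

    Hazards are per day; C1 carries the highest hazard, response
    probability and mutation rate, mirroring an aggressive-but-
    immunotherapy-responsive group versus two indolent groups.
    """

    clusters: tuple[str, ...] = ("C1", "C2", "C3")
    proportions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    signature_size: int = 20
    signature_shift: float = 2.0  # in units of the log-expression sd
    log_sd: float = 1.0
    log_mean: float = 3.0
    hazards: tuple[float, ...] = (1 / 400.0, 1 / 900.0, 1 / 1200.0)
    response_probs: tuple[float, ...] = (0.6, 0.25, 0.2)
    mutation_rates: tuple[float, ...] = (150.0, 60.0, 50.0)
    censoring_fraction: float = 0.3
    signature_genes: dict[str, list[str]] | None = None  # explicit override


# ---------------------------------------------------------------------------
# Single-cell generator
# ---------------------------------------------------------------------------


def _gene_names(n_genes: int, n_tfs: int) -> tuple[list[str], list[str]]:
    tfs = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    others = [f"G{i + 1:04d}" for i in range(n_genes - n_tfs)]
    return tfs, others


def generate_single_cell_cohort(
    n_cells: int = 1500,
    n_genes: int = 800,
    n_tfs: int = 40,
    n_hubs: int = 8,
    lineage_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    *,
    effect: float = 8.0,
    baseline: float = 3.0,
    dispersion: float = 0.2,
    dropout: float = 0.1,
    cell_noise: float = 0.4,
    hub_targets: int = 35,
    nonhub_targets: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticSingleCellTruth]:
    """Simulate a genes x cells count matrix with planted regulons.

    Each TF carries one activity level per lineage: a per-TF base level
    drawn on [0.3, 0.7] plus independent lineage offsets on [-0.2, 0.2].
    The TF's realised activity in cell ``c`` is its lineage level plus a
    shared per-cell fluctuation (sd ``cell_noise``, clipped to [0, 1]) —
    transcription-factor activity varies cell to cell, and that
    fluctuation, being unique to the regulon, is what lets a correlation
    screen tell one regulon's targets from another's.  A cell's expected
    count for the TF and each of its targets is
    ``baseline * (1 + effect * activity)``.  Counts are
    negative binomial (variance mu + dispersion*mu^2) with independent
    zero-inflation at rate ``dropout``.  Hub TFs regulate
    ``hub_targets`` genes, non-hubs ``nonhub_targets``; target sets are
    disjoint.
    """
    if min(n_cells, n_genes, n_tfs, n_hubs) <= 0:
        raise ValueError("all dimensions must be positive")
    if not (n_hubs < n_tfs < n_genes):
        raise ValueError("require n_hubs < n_tfs < n_genes")
    if n_cells < 30:
        raise ValueError("n_cells must be at least 30")
    if abs(sum(lineage_fractions) - 1.0) > 1e-9:
        raise ValueError("lineage fractions must sum to 1 within 1e-9")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must lie in [0, 1)")
    n_targets_needed = n_hubs * hub_targets + (n_tfs - n_hubs) * nonhub_targets
    if n_targets_needed > n_genes - n_tfs:
        raise ValueError("not enough non-TF genes for the requested regulon sizes")

    rng = np.random.default_rng(seed)
    tf_names, other_names = _gene_names(n_genes, n_tfs)
    genes = tf_names + other_names

    # lineage assignment (deterministic rounded block sizes, then shuffled)
    counts = np.floor(np.asarray(lineage_fractions) * n_cells).astype(int)
    counts[0] += n_cells - counts.sum()
    lineage_arr = np.repeat(np.arange(3), counts)
    rng.shuffle(lineage_arr)
    cells = [f"cell{i + 1:05d}" for i in range(n_cells)]
    lineages = pd.Series(
        [LINEAGES[i] for i in lineage_arr], index=cells, name="lineage"
    )

    # planted regulons: disjoint target sets, hubs first
    pool = list(other_names)
    rng.shuffle(pool)
    hub_tfs = tf_names[:n_hubs]
    regulons: list[PlantedRegulon] = []
    cursor = 0
    for tf in tf_names:
        size = hub_targets if tf in hub_tfs else nonhub_targets
        targets = tuple(pool[cursor : cursor + size])
        cursor += size
        # per-TF base level plus modest lineage offsets: lineage structure
        # is real but weaker than the per-cell activity fluctuation, as in
        # regulons whose activity varies more cell-to-cell than by lineage
        base = rng.uniform(0.3, 0.7)
        activity = {
            lin: float(np.clip(base + rng.uniform(-0.2, 0.2), 0.0, 1.0))
            for lin in LINEAGES
        }
        regulons.append(PlantedRegulon(tf, targets, activity))

    # per-gene, per-cell realised activity of the regulating TF
    # (0 for noise genes); the per-cell fluctuation is shared across a
    # regulon, coupling the TF with its targets beyond the lineage factor
    gene_idx = {g: i for i, g in enumerate(genes)}
    act = np.zeros((n_genes, n_cells))
    for reg in regulons:
        a_lin = np.array([reg.activity[lin] for lin in LINEAGES])
        a_cell = a_lin[lineage_arr]
        if cell_noise > 0:
            a_cell = np.clip(a_cell + cell_noise * rng.standard_normal(n_cells), 0, 1)
        act[gene_idx[reg.tf]] = a_cell
        for t in reg.targets:
            act[gene_idx[t]] = a_cell

    mu = baseline * (1.0 + effect * act)  # genes x cells
    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mu)
        mat = rng.negative_binomial(r, p)
    else:
        mat = rng.poisson(mu)
    if dropout > 0:
        mat = mat * (rng.random(mat.shape) >= dropout)

    expr = pd.DataFrame(mat, index=genes, columns=cells)
    truth = SyntheticSingleCellTruth(
        regulons=regulons,
        lineage_of_cell=lineages.to_dict(),
        planted_hub_tfs=list(hub_tfs),
    )
    return expr, lineages, truth


def generate_immune_gene_list(
    truth: SyntheticSingleCellTruth,
    n_decoys: int,
    seed: int = 0,
    gene_universe: list[str] | None = None,
) -> list[str]:
    """Planted hub TFs plus ``n_decoys`` non-hub genes drawn uniformly.

    Emulates an immune-related gene list that contains the true drivers
    among many genes irrelevant to the planted networks.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be non-negative")
    hubs = list(truth.planted_hub_tfs)
    if gene_universe is None:
        universe = {r.tf for r in truth.regulons}
        for r in truth.regulons:
            universe.update(r.targets)
        gene_universe = sorted(universe)
    non_hub = [g for g in gene_universe if g not in set(hubs)]
    if n_decoys > len(non_hub):
        raise ValueError("n_decoys exceeds the number of available non-hub genes")
    rng = np.random.default_rng(seed)
    decoys = list(rng.choice(non_hub, size=n_decoys, replace=False))
    return hubs + sorted(decoys)


def hub_signature_sets(
    truth: SyntheticSingleCellTruth,
    clusters: tuple[str, ...] = ("C1", "C2", "C3"),
    targets_per_hub: int = 8,
) -> dict[str, list[str]]:
    """Partition the planted hub TFs (and a slice of their targets) into
    disjoint per-cluster signature sets, so that a bulk cohort generated
    with them carries its cluster signal on driver genes."""
    hubs = list(truth.planted_hub_tfs)
    by_tf = {r.tf: r for r in truth.regulons}
    sigs: dict[str, list[str]] = {}
    for i, c in enumerate(clusters):
        members: list[str] = []
        for h in hubs[i :: len(clusters)]:
            members.append(h)
            members.extend(by_tf[h].targets[:targets_per_hub])
        sigs[c] = members
    return sigs


# ---------------------------------------------------------------------------
# Bulk cohort generator
# ---------------------------------------------------------------------------


def _censoring_horizon(hazards: np.ndarray, weights: np.ndarray, frac: float) -> float:
    """Upper bound u of Uniform(0, u) censoring giving the target censored
    fraction under a mixture of exponential event times (closed-form root)."""

    def censored_prob(u: float) -> float:
        x = hazards * u
        return float(np.sum(weights * (1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e8
    return brentq(lambda u: censored_prob(u) - frac, lo, hi, xtol=1e-6)


def generate_bulk_cohort(
    n_samples: int = 150,
    n_genes: int = 800,
    spec: CohortSpec | None = None,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticCohortTruth]:
    """Simulate a bulk cohort with planted expression clusters.

    Returns (expression genes x samples, clinical table, MAF-lite mutation
    table, truth).  Expression is log-normal; each cluster's signature
    genes get a ``signature_shift`` (in sd of the log scale) mean bump in
    that cluster.  Survival is exponential per cluster with independent
    Uniform(0, u) administrative censoring calibrated to the requested
    censored fraction; response labels are Bernoulli per cluster mapped
    onto CR/PR (responders) and SD/PD (non-responders); mutation counts
    are Poisson per cluster expanded to one row per variant.
    """
    spec = spec or CohortSpec()
    k = len(spec.clusters)
    if n_samples < 3 * k:
        raise ValueError("need at least 3 samples per cluster")
    rng = np.random.default_rng(seed)

    if gene_names is not None:
        if len(set(gene_names)) != len(gene_names):
            raise ValueError("gene_names must be unique")
        genes = list(gene_names)
        n_genes = len(genes)
    else:
        genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]

    # cluster assignment
    counts = np.floor(np.asarray(spec.proportions) * n_samples).astype(int)
    counts[0] += n_samples - counts.sum()
    labels = np.repeat(np.arange(k), counts)
    rng.shuffle(labels)
    cluster_of_sample = {s: spec.clusters[labels[i]] for i, s in enumerate(samples)}

    # signature gene sets (disjoint)
    if spec.signature_genes is not None:
        signature_genes = {c: list(v) for c, v in spec.signature_genes.items()}
        for c, sig in signature_genes.items():
            if not sig:
                raise ValueError(f"empty signature set for cluster {c}")
            missing = set(sig) - set(genes)
            if missing:
                raise ValueError(f"signature genes absent from universe: {missing}")
    else:
        if spec.signature_size <= 0:
            raise ValueError("empty signature set")
        if k * spec.signature_size > n_genes:
            raise ValueError(
                f"{k} signatures of {spec.signature_size} genes exceed the "
                f"{n_genes}-gene universe"
            )
        picked = rng.choice(genes, size=k * spec.signature_size, replace=False)
        signature_genes = {
            c: sorted(
                str(g)
                for g in picked[i * spec.signature_size : (i + 1) * spec.signature_size]
            )
            for i, c in enumerate(spec.clusters)
        }

    gene_idx = {g: i for i, g in enumerate(genes)}
    shift = np.zeros((len(genes), n_samples))
    for i, c in enumerate(spec.clusters):
        cols = labels == i
        for g in signature_genes[c]:
            shift[gene_idx[g], cols] = spec.signature_shift * spec.log_sd
    log_expr = rng.normal(spec.log_mean, spec.log_sd, size=shift.shape) + shift
    expr = pd.DataFrame(np.exp2(log_expr), index=genes, columns=samples)

    # survival with administrative uniform censoring
    hazards = np.asarray(spec.hazards)[labels]
    event_time = rng.exponential(1.0 / hazards)
    u = _censoring_horizon(
        np.asarray(spec.hazards), counts / n_samples, spec.censoring_fraction
    )
    censor_time = rng.uniform(0.0, u, size=n_samples)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # response labels
    probs = np.asarray(spec.response_probs)[labels]
    responder = rng.random(n_samples) < probs
    pos = np.where(rng.random(n_samples) < 0.5, "CR", "PR")
    neg = np.where(rng.random(n_samples) < 0.5, "SD", "PD")
    response = np.where(responder, pos, neg)

    stage = rng.choice(["I", "II", "III", "IV"], size=n_samples)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "time": time,
            "event": event,
            "response": response,
            "stage": stage,
            "cluster_truth": [cluster_of_sample[s] for s in samples],
        }
    )

    # mutations (MAF-lite)
    class_pool = tuple(sorted(NONSYNONYMOUS_CLASSES)) + SYNONYMOUS_CLASSES
    class_probs = np.array([0.8 / len(NONSYNONYMOUS_CLASSES)] * len(NONSYNONYMOUS_CLASSES)
                           + [0.2 / len(SYNONYMOUS_CLASSES)] * len(SYNONYMOUS_CLASSES))
    rates = np.asarray(spec.mutation_rates)[labels]
    rows = []
    for i, s in enumerate(samples):
        m = rng.poisson(rates[i])
        if m == 0:
            continue
        mut_genes = rng.choice(genes, size=m, replace=True)
        mut_classes = rng.choice(class_pool, size=m, p=class_probs)
        rows.extend(zip([s] * m, mut_genes, mut_classes))
    mutations = pd.DataFrame(
        rows, columns=["sample", "gene", "variant_classification"]
    )

    truth = SyntheticCohortTruth(
        cluster_of_sample=cluster_of_sample,
        signature_genes=signature_genes,
        hazard_of_cluster=dict(zip(spec.clusters, spec.hazards)),
        response_prob_of_cluster=dict(zip(spec.clusters, spec.response_probs)),
        mutation_rate_of_cluster=dict(zip(spec.clusters, spec.mutation_rates)),
    )
    return expr, clinical, mutations, truth
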