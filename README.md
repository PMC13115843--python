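# grndriver

Network-centrality prioritisation of immune-related candidate driver
genes from cell-lineage gene regulatory networks (GRNs), and
stratification of a patient cohort on those genes — as one tested,
reproducible pipeline.

The package is aimed at computational biologists studying tumor
immunology: given a single-cell expression matrix with cell-lineage
labels, it infers (or ingests) TF→target regulons, scores per-cell
regulon activity, ranks every network gene by fusing five centrality
indices into a single order-statistics score, and intersects the top
genes with an immune gene list. The resulting driver genes then
stratify a bulk cohort by consensus clustering, with cluster number
chosen from the consensus-CDF delta area, cross-cohort reproducibility
measured by the in-group proportion (IGP), per-sample cluster signature
scores by ssGSEA, and survival / response / mutation-burden statistics.
A synthetic-data module generates every input with planted ground truth
so the whole pipeline is testable offline.

## The core statistic

For each node of the GRN, five centrality indices are computed
(degree, betweenness, eigenvector, PageRank, closeness) and converted
to rank ratios r_i = rank_i / n ∈ (0, 1]. The indices are fused by the
order-statistics **Q statistic**

    Q(r_1, …, r_N) = P(U_(1) ≤ r_(1), …, U_(N) ≤ r_(N)),

the probability that the order statistics of N iid Uniform(0, 1)
variables jointly fall below the sorted observed ratios, evaluated by
the recursion

    V_k = Σ_{j=1..k} (−1)^{j−1} (V_{k−j} / j!) · r_{N−k+1}^j,
    V_0 = 1,   Q = N! · V_N.

A gene ranked near the top on every index gets a very small Q (Q
behaves as a joint p-value), so genes with a top-5 % Q that also appear
in the immune gene list become immune-related candidate driver genes.
See `docs/methods.md` for the full model description.

## Worked example

Generate a synthetic study (1 500 cells, 800 genes, 8 planted hub TFs;
a 150-sample bulk cohort with three planted clusters riding on the hub
regulons) and run the full pipeline:

```bash
grndriver simulate --out-dir study --seed 0

cat > config.yaml <<EOF
expression: study/sc_expression.tsv
tf_list: study/tf_list.txt
immune_list: study/immune_list.txt
bulk_expression: study/bulk_expression.tsv
clinical: study/clinical.tsv
mutations: study/mutations.tsv
seed: 0
output_dir: run
EOF

grndriver run-all --config config.yaml
```

The run directory then contains, among other artifacts:

`run/drivers.txt` — the selected driver genes. All 8 planted hubs are
recovered, plus three immune-list decoys that sit in the network's top
5 %:

```
G0395 G0580 G0737 TF001 TF002 TF003 TF004 TF005 TF006 TF007 TF008
```

`run/k_selection.tsv` — the consensus-CDF area A(k) and delta area
Δ(k); k = 3 is the largest k with Δ(k) ≥ 0.05, matching the three
planted clusters:

```
k   cdf_area  delta_area  chosen
2   0.4446    0.4446      0
3   0.6711    0.5094      1
4   0.6824    0.0170      0
5   0.6971    0.0214      0
6   0.7185    0.0308      0
```

`run/statistics.tsv` — the clusters differ strongly in survival
(log-rank χ² = 38.7, p = 4.0e−9) and mutation burden (Kruskal–Wallis
H = 108.1, p = 3.3e−24), and one cluster's signature score is strongly
associated with immunotherapy response (Wilcoxon p = 5.2e−6, responders
higher) — the planted aggressive/responsive cluster.

Every stage is also available as its own subcommand (`simulate`,
`infer-grn`, `drivers`, `cluster`, `score`, `stats`), and everything is
importable as a library (`import grndriver`). Rerunning `run-all` with
the same config and seed reproduces every artifact bitwise; the
manifest records input checksums, parameters and the seed.

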