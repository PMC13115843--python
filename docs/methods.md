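# Methods

`grndriver` re-implements, as a reusable and fully testable pipeline, a
network-based strategy for finding immune-related candidate driver genes
in cell-lineage gene regulatory networks (GRNs) and using them to
stratify a patient cohort. This note records the models, the defaults
and the design decisions, in the order the method runs.

## 1. Regulons and the gene regulatory network

A *regulon* is a transcription factor (TF) together with its inferred
target genes. Regulons are either ingested from a `(tf, target, weight)`
edge table or inferred from a genes × cells expression matrix with a
Spearman-correlation screen: for each TF, all other genes are ranked by
|ρ| against the TF across cells; the `top_n_targets` (default 50)
strongest correlates with |ρ| ≥ `min_abs_rho` (default 0.2) are kept,
and modules with fewer than `min_module_size` genes (default 21, i.e.
strictly more than 20) are discarded. The screen deliberately stands in
for gradient-boosted GRN inference followed by motif pruning: the
downstream analysis consumes only the edge list, and a correlation
screen is the simplest inference whose failure modes are fully
understood on synthetic data. A constant-expression TF has undefined
correlations and is skipped with a warning. The union of all regulon
edges forms a directed graph (no self-loops, duplicate edges collapsed
keeping the maximum weight).

## 2. Regulon activity (recovery AUC)

Per-cell regulon activity is the AUCell-style recovery AUC with an AUC
threshold of 0.05. For each cell, genes are ranked by descending
expression; ties are broken by a deterministic seeded permutation per
cell, so sparse count data yield reproducible activities. The recovery
curve counts regulon genes among the top k ranks for
k = 1..⌈0.05·G⌉; activity is the area under that curve divided by the
maximum achievable area (all regulon genes at the very top), hence lies
in [0, 1] and is invariant to any strictly monotone transform of a
cell's expression. Regulon genes absent from the matrix are dropped
with a logged count; a regulon with no genes present is an error.

## 3. Centrality fusion: the Q statistic

Five centrality indices are computed per network node:

* **degree** — total in + out edge count (a hub TF scores on out-degree,
  a heavily regulated target on in-degree; both compete in one ranking);
* **betweenness** — fraction of directed shortest paths through the
  node, endpoints excluded, normalised by (n−1)(n−2);
* **PageRank** — damping 0.85, uniform teleport, iterated far below the
  1e−9 convergence target;
* **eigenvector** and **closeness** — computed on the undirected
  projection. Directed GRNs are nearly bipartite, so the directed
  eigenvector degenerates to zero outside strongly connected components
  and most directed node pairs are mutually unreachable; the undirected
  projection keeps both indices informative. Closeness uses the
  component-scaled (Wasserman–Faust) form. Edge weights are ignored
  throughout; the indices are topological.

Per index, nodes are ranked descending (largest centrality = rank 1,
ties averaged) and converted to rank ratios r_i = rank/n ∈ (0, 1]. The
N = 5 ratios are fused with the order-statistics **Q statistic**: the
probability that the order statistics of N iid Uniform(0, 1) draws
jointly fall below the sorted observed ratios,

    Q(r) = P(U_(1) ≤ r_(1), …, U_(N) ≤ r_(N)).

A gene near the top of every ranking has a very small Q; Q behaves as a
joint p-value against "uninteresting on all indices", so smaller is
better. Q is evaluated by the recursion V_k = Σ_{j=1..k} (−1)^{j−1}
(V_{k−j}/j!) · r_{N−k+1}^j with V_0 = 1 and Q = N!·V_N, implemented in
the scaled form W_k = k!·V_k, W_k = Σ_j (−1)^{j−1} C(k,j) W_{k−j}
r_{N−k+1}^j, which is algebraically identical but free of factorial
overflow at any N. The recursion is validated in the tests against
closed forms (Q(r)=r for N=1; Q(0.5, 1.0)=0.75; Q(0.5, 0.5)=0.25) and a
Monte-Carlo order-statistic oracle.

**Driver selection.** Genes with Q at or below the ⌈0.05·n⌉-th smallest
value (`top_fraction` = 0.05) are intersected with an immune gene list
to give the immune-related candidate driver set. The quantile is taken
over all network nodes by default (the Q ranking is a property of the
network; immunity filters afterwards); a `scope="immune_only"` flag
computes the quantile over immune genes only, since both readings are
defensible. Ties at the cutoff are included; an empty intersection is a
valid, logged result. Tie-averaged ranks were chosen over arbitrary tie
orders so that equal centralities give equal Q.

## 4. Patient stratification

**Consensus clustering** (Monti resampling): `n_resamples` = 500 draws
of 80 % of samples without replacement; each subsample is clustered by
average-linkage agglomerative clustering on 1 − Pearson correlation
distance; consensus(i, j) = co-clustering count / co-sampling count.
Final labels per k come from average-linkage clustering of
1 − consensus. The resampling scheme, inner clusterer and distance are
configurable; the defaults mirror the common defaults of the
consensus-clustering tools used in practice. Runs are fully
deterministic given the seed.

**Choice of k** uses the CDF delta-area rule: A(k) is the area under
the empirical CDF of the upper-triangle consensus values; Δ(k) = A(k)
for the smallest k, and (A(k) − A(k−1))/A(k−1) afterwards; the chosen k
is the largest k with Δ(k) ≥ 0.05, falling back to the smallest k when
nothing qualifies (a degenerate single-cluster cohort).

**Cross-cohort reproducibility (IGP).** Genes are intersected across
cohorts and z-scored per cohort to remove cohort-level scale.
Validation samples are assigned to the nearest reference-cluster
centroid by Pearson correlation; the in-group proportion of cluster g
is the fraction of its assigned samples whose nearest validation
neighbour (correlation, excluding self) is assigned to g too. A cluster
with fewer than two assigned samples has an undefined IGP (reported
missing). Note that under a pure-noise validation cohort the raw IGP
sits visibly above 0.5: the centroid assignment is a hyperplane split
and near neighbours tend to fall on the same side. Raw IGP is therefore
only interpretable against the permuted-centroid null (permute centroid
gene labels B times), which the implementation provides as an optional
permutation p-value; the test suite checks both the bias and the
calibration of the null.

## 5. Scoring and statistics

**ssGSEA.** Per sample, genes are ranked by descending expression; the
score of a gene set is the sum over all positions of the running
difference between the weighted in-set ECDF (an in-set gene at position
i from the top contributes weight (G − i)^α, α = 0.25) and the uniform
out-of-set ECDF. The score depends only on ranks, hence is invariant to
strictly monotone per-sample transforms. Optional normalisation divides
the whole matrix by its global score range; both modes are exposed
because published analyses are split on this. The implementation is
deliberately the rank-weighted variant — value-weighted variants are
not monotone-transform invariant — and is verified against a literal
position-by-position enumeration in the tests.

**Statistical layer.** Wilcoxon rank-sum (exact for small tie-free
samples, tie/continuity-corrected normal approximation otherwise) for
two groups; Kruskal–Wallis (tie-corrected) for three or more;
Benjamini–Hochberg step-up FDR; log-rank across survival curves;
Spearman correlation. These delegate to scipy, statsmodels and
lifelines behind a stable module surface, and their type-I error at
nominal 0.05 is checked by null simulation. TMB is the per-sample count
of nonsynonymous variants (missense, nonsense, frameshift ins/del,
splice site, in-frame ins/del, translation start site, nonstop — an
explicit, configurable class list); the mutated-gene count counts
distinct genes with at least one such variant. Differential expression
per gene uses Wilcoxon with log2FC defined as the difference of group
means of log2(x + 1) (the +1-log convention is a declared choice).
Response association compares responders (CR ∪ PR) against
non-responders (SD ∪ PD) by default.

## 6. Synthetic study conditions

The generators produce every input the pipeline consumes plus ground
truth, at a scale (~2 orders below the motivating data) where all
property tests run in seconds.

**Single-cell cohort** — defaults: 1 500 cells, 800 genes, 40 TFs of
which 8 are hubs, lineage fractions (0.50, 0.25, 0.25) over lymphoid /
myeloid / tumor. Hubs regulate 35 targets, non-hubs 6 (≥ 5× median, so
hubs are unambiguous topological drivers); target sets are disjoint.
Each TF has a per-lineage activity level: a per-TF base in [0.3, 0.7]
plus independent lineage offsets in [−0.2, 0.2]. The activity realised
in a cell adds a per-cell fluctuation shared by the whole regulon
(normal, sd `cell_noise` = 0.4, clipped to [0, 1]) — TF activity varies
from cell to cell, and that shared fluctuation is precisely the signal
a co-expression screen uses to tell one regulon's targets from
another's. This matters: with activity varying only across three
discrete lineages, any two TFs with similar lineage profiles produce
statistically identical target profiles and no screen can sort their
targets apart (edge recall saturates near 30 % regardless of effect
size); the per-cell fluctuation removes that degeneracy, and the
measured separation (cross-regulon |ρ| at most ≈ 0.11 vs own-regulon
|ρ| almost surely above 0.25) is what the `min_abs_rho` = 0.2 default
threads. Counts are negative binomial with mean
baseline·(1 + effect·activity) (baseline 3, effect 8, dispersion 0.2,
variance μ + 0.2μ²) with independent zero-inflation (dropout 0.1).
What the generator does **not** emulate: batch effects, doublets,
library-size variation, copy-number signal, TF→TF regulation and
shared targets. Passing tests therefore show that the pipeline recovers
planted topology under realistic count noise — not that correlation
inference succeeds on real tissue.

**Bulk cohort** — defaults: 150 samples in three equal planted clusters
C1–C3; log-normal expression (log2 scale, sd 1) with disjoint 20-gene
signatures shifted by 2 sd in their cluster; exponential survival with
hazards (1/400, 1/900, 1/1200) per day — C1 the aggressive,
high-burden, immunotherapy-responsive group — under uniform
administrative censoring whose horizon is solved in closed form to give
30 % censoring; responder probability (0.6, 0.25, 0.2) mapped onto
CR/PR vs SD/PD; mutation counts Poisson (150, 60, 50) expanded into
MAF-lite rows (80 % nonsynonymous classes). `hub_signature_sets` plants
the bulk signatures on the hub regulons of a single-cell truth so the
driver genes found on the network side genuinely stratify the cohort.
The immune gene list is the planted hubs plus uniformly drawn decoys
(default 50).

Every generator takes one explicit seed and owns one
`numpy.random.Generator`; identical seeds reproduce all outputs
bitwise.

## 7. Numerical and degenerate-case choices

* Q recursion in binomial form (above); closed-form checks to 1e−12.
* PageRank iterated to an L1 tolerance of n·1e−12 so it agrees with a
  dense linear solve to better than 1e−8.
* Eigenvector centrality via a dense symmetric eigendecomposition
  (sign-fixed, L2-normalised); the tests cross-check with power
  iteration and generate graphs with a simple leading eigenvalue so
  the comparison is well posed.
* Consensus matrices are symmetrised and get a unit diagonal; a sample
  pair never co-sampled raises with guidance to increase `n_resamples`.
* Constant profiles get zero correlation distance contributions rather
  than NaN; constant genes/vectors in correlation analyses are reported
  missing, not errors.
* The pipeline manifest records input checksums, parameters and the
  seed, but not the output directory, so "equal manifests ⇒ equal
  outputs, bitwise" holds exactly.
* Cluster signatures inside the pipeline are derived from mean
  log2(x+1) differences (one vs rest) rather than per-gene tests, so
  they remain defined for arbitrarily small consensus clusters.

## 8. Known limitations

* The correlation screen cannot orient edges or separate direct from
  indirect regulation; it inherits all the usual caveats of
  co-expression GRNs.
* Q assumes the N rank ratios are independent under the null; real
  centrality indices are correlated, so Q is a fusion score, not a
  calibrated p-value. No significance calibration against network
  randomisation is attempted.
* The delta-area rule for k is a deterministic elbow heuristic; on
  cohorts without block structure it falls back to the smallest k
  rather than abstaining.
* IGP without its permutation null overstates reproducibility (Section
  4); consumers should report the p-value alongside the raw value.
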