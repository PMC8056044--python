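# Methods

## Model and procedure

The pipeline prioritizes disease genes in three stages.

**1. Positive-unlabeled reprioritization.**  The positive set P is the
risk-GWAS genes with gene-level p < α (α = 0.01 by default, strict
inequality), intersected with the network's node set; genes in the
p-value table but absent from the network have undefined features and
are dropped with a logged count.  Features are raw edge weights to the
positives, unscaled — weights already live in [0, 1] — and a positive's
own column is 0 because the network has no self-loops.  Each of the
`n_models` ensemble members trains a linear soft-margin SVM (libsvm via
scikit-learn's `SVC(kernel="linear")`) on all positives against an
independently resampled balanced set of unlabeled genes; the cost C is
selected from {0.01, 0.1, 1, 10, 100} by 5-fold stratified CV on
held-out ROC AUC.  The grid, fold count and selection metric are
package conventions: they are the standard choices for a linear SVM
cost search, and results are insensitive to them on the benchmark.

Per-model decision values are normalized to the
unlabeled-predicted-positive rate (UPPR) — the fraction of non-tied
unlabeled genes scoring above the gene — and averaged over models;
FS = −log10(mean UPPR).  UPPR is computed against *all* unlabeled
genes, including those sampled as a model's negatives: the negatives
are a modeling device, not a label.  Positives also receive UPPRs (and
hence FS), so every network gene is scored.

**2. Joint-CDF integration.**  PS = −log10(p) from the endophenotype
GWAS; CS is the empirical joint CDF evaluated with strict inequalities
on both axes, over the N genes that have both an FS and a PS.  Ties
never dominate each other, CS ∈ [0, (N−1)/N], and any strictly
increasing transform of either axis leaves every CS unchanged — so CS
is a rank-based quantity, not a parametric one.

**3. Module analysis.**  The subnetwork keeps genes with FS > 2 and
edges with weight > 0.25; the same filtered graph that would be
visualized is the graph analyzed (both thresholds are configurable, so
filtering only for display is also expressible).  Isolated nodes are
retained.  Louvain modularity maximization (resolution 1.0, seeded)
partitions the subgraph; module labels are renumbered by descending
size for stable reports, and the returned partition is floored at the
better of the all-singletons / single-module baselines.

## Numerical choices

* **UPPR ties.**  Both counts use strict inequalities; a gene tied with
  every unlabeled gene has an empty denominator and is assigned 0.5,
  the uninformative midpoint (continuous with the half-rank
  convention).
* **FS cap.**  A mean UPPR of exactly 0 (the gene beat every unlabeled
  gene in every model) is floored at 0.5/|U| before the logarithm, a
  half count out of |U|, keeping FS finite for the joint CDF.  The
  FS = 2 ⇔ mean UPPR = 0.01 equivalence is unaffected whenever
  |U| > 50.
* **Combined-score algorithm.**  The production path sorts by FS and
  sweeps a Fenwick tree over dense PS ranks, processing FS-tie groups
  as blocks (queried before insertion) so within-block genes never
  dominate each other; it is exactly equal — not approximately — to the
  O(N²) brute-force transcription of the definition, which is kept in
  the package as `combined_score_bruteforce` and asserted against in
  the tests.
* **Ranking ties.**  Equal CS is broken by PS, then FS (descending),
  then gene id, so top-k tables are deterministic.
* **Determinism.**  One global seed drives everything: synthetic draws,
  per-model negative samples and CV folds (derived via
  `SeedSequence([seed, model_index, stream])`), and Louvain's node
  order.  Reruns are byte-identical.

## Synthetic data generator

The generator emulates the structure the method exploits: a sparse
weighted network in which a planted disease module has denser
(`edge_density_within` = 0.3) and heavier (Beta(8, 2), mean 0.8) edges
than the background (density 0.02, Beta(2, 8), mean 0.2); a risk
p-value table in which signal genes draw p ~ Beta(a, 1) with a = 0.1
(so P(p < 0.01) = 0.01^0.1 ≈ 0.63) and all other genes are Uniform(0,1);
and an endophenotype table whose signal set overlaps the risk signal by
`overlap_frac` (default 0.5), with the remainder drawn from unlabeled
module genes and then background.  `contamination_frac` of the risk
signal can be diverted to background genes to model false-positive
GWAS hits.  Non-sampled pairs are absent, not zero-weight edges,
matching sparse `*_top` network releases; absent edges contribute 0 to
feature vectors.

The benchmark condition — 3,000 genes, one 150-gene module, 100 module
genes with risk signal, 50 held out — is small enough to run the full
pipeline in seconds yet large enough that the held-out recovery AUC is
a meaningful statistic.  What the generator does **not** model: linkage
disequilibrium between neighboring genes (real gene-level p-values are
locally correlated), degree heterogeneity and hub structure of real
functional networks, multiple overlapping pathways per gene, and any
SNP-level process (generation starts at the gene level).  Passing the
recovery benchmark therefore demonstrates that the implementation
correctly exploits module structure under the model's assumptions, not
that the method attains the same accuracy on real tissue networks.

The Beta weight parameters are a modeling choice: the weight
distribution of real tissue networks is not characterized here, so the
within/background contrast is chosen to give a clear but not trivial
separation signal.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.01 | gene-level p-value cutoff defining positives |
| `n_models` | 100 (25 in the benchmark scripts) | ensemble size; variance of mean UPPR shrinks as 1/√n |
| `c_grid` | {0.01…100} | SVM cost grid searched per model |
| `fs_threshold` | 2 | subnetwork membership, equivalent to mean UPPR < 0.01 |
| `edge_min` | 0.25 | edge filter before modularity / visualization |
| `overlap_frac` | 0.5 | risk/endo signal overlap in the generator |

The benchmark scripts use 25 models rather than the 100 the package
defaults to: on the synthetic benchmark the recovery AUC is already
saturated at 25, and the ensemble-mean UPPR is stable enough for every
downstream stage.

## Degenerate inputs and errors

Empty positive selections, single-class or all-identical training
sets, p-values outside (0, 1], self-loops, duplicate edges or gene
ids, fewer than two jointly scored genes, and partitions that do not
cover the graph all raise typed validation errors naming the offending
field, gene, or file line.  Pipeline failures abort with the failing
stage named in the exception and recorded in the partial manifest.

## Known limitations

* With only positive labels, FS is a relative ranking, not a
  calibrated probability; the UPPR's analogy to a false-positive rate
  holds only under the PU assumption that unlabeled genes are mostly
  negative.
* CS has no attached significance level; top-k reporting is the only
  selection mechanism, and no FDR is assigned.
* The Louvain heuristic is seed-dependent on graphs with many
  near-optimal partitions; only the seeded result is reported, along
  with Q, so alternative partitions of near-equal quality may exist.
* Functional annotation of modules requires live annotation databases
  and is out of scope; the package exports per-module ranked gene
  lists for external enrichment tools instead.
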