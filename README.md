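# netprio

Network-based prioritization of GWAS risk genes, with integration of an
endophenotype GWAS through an empirical joint-CDF combined score.

## The problem

Case-control GWAS for complex diseases leave most true risk genes below
genome-wide significance.  At a liberal threshold (gene-level p < 0.01)
the hit list captures many more true positives — mixed with false
positives that p-values alone cannot separate.  Because true risk genes
tend to be functionally related to one another, a tissue-specific
functional network can re-rank the genome: genes strongly connected to
the nominally significant set are likely real.  When a second,
biologically proximal GWAS (an endophenotype such as a brain-structure
volume) is available, genes scoring highly on *both* axes are the best
candidates for mechanism-specific risk.

`netprio` implements this pipeline for anyone with (a) a weighted
functional gene network (e.g. a HumanBase `*_top` edge list), (b) a
gene-level p-value table for the risk GWAS (e.g. MAGMA output), and
(c) a gene-level p-value table for the endophenotype GWAS.  A synthetic
generator with planted disease modules makes the whole pipeline
testable without any download.

## The method

**Network-based gene reprioritization (NGR).**  Positive examples are
the risk-GWAS genes with p < α (default 0.01).  Every network gene g
gets the feature vector f_g = [W_{g p_1}, …, W_{g p_n}] of edge weights
to the n positives (0 where no edge).  An ensemble of linear
soft-margin SVMs is trained — each model uses all positives against an
independent balanced random sample of unlabeled genes as putative
negatives (positive-unlabeled learning), with the cost C chosen by
stratified cross-validation.  Each model's decision values are
normalized to the unlabeled-predicted-positive rate

    UPPR_ij = #{g ∈ U : M_i(g) > M_i(g_j)}
              ─────────────────────────────────────────────────
              #{g ∈ U : M_i(g) > M_i(g_j)} + #{g ∈ U : M_i(g_j) > M_i(g)}

(U = unlabeled genes; strict inequalities, ties excluded from both
counts), and aggregated into the functional score

    FS(g_j) = −log10( mean_i UPPR_ij ),

so FS > 2 ⇔ mean UPPR < 0.01.

**Score integration.**  With the positional score PS(g) = −log10(p_g)
from the endophenotype GWAS, the combined score is the empirical joint
CDF at the gene's score pair:

    CS(g_j) = #{g : FS(g) < FS(g_j) and PS(g) < PS(g_j)} / N

— the probability that a random gene scores strictly lower on both
axes.

**Module analysis.**  The subnetwork of genes with FS > 2, filtered to
edges with weight > 0.25, is partitioned by seeded Louvain modularity
maximization; per-module ranked gene lists are exported for enrichment
tools.

## Worked example

The numbered scripts under `analysis/` run the full benchmark on
synthetic data (3,000 genes, one planted 150-gene disease module, 100
module genes with risk-GWAS signal):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_reprioritize.py --seed 1
python analysis/03_integrate_scores.py
python analysis/04_network_modules.py --seed 1
```

Step 02 prints

```
positives: 96 genes at p < 0.01
functional scores written for 3000 genes (36 with FS > 2)
held-out planted vs background AUC: 0.9989 (50 vs 2819 genes)
```

— the 96 nominally significant genes seed the ensemble, and the 50
planted genes that were *never* given GWAS signal are almost perfectly
separated from the 2,819 background genes purely by their network
connectivity (AUC 0.9989).  Step 03 then reports that all of the top-10
combined-score genes come from the planted module, e.g.

```
             FS       PS      CS
G000093  2.1963  17.0493  0.9947
G000016  2.9114   8.0893  0.9930
```

(G000093 scores lower than 0.53% of genes on neither axis), and step 04
partitions the 36-gene FS > 2 subnetwork into 4 modules, all planted:

```
subnetwork (FS > 2.0, w > 0.25): 36 genes, 244 edges
4 modules, Q = 0.1394
```

The same stages are available as a CLI (`netprio synth|ngr|combine|
modules|all`) driven by a YAML config with a single global seed; see
`netprio --help`.

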