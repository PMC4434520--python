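# chipsig

Post-peak-calling analysis of multi-library ChIP-seq co-occupancy, built
around the regulatory signature of the t(8;21) fusion protein AML1-ETO:
loci where the fusion protein co-localizes with the co-repressor N-CoR
behave differently — in chromatin state, motif content, and knockdown
response — from loci marked by active-promoter chromatin.  `chipsig`
implements the full downstream workflow as a tested Python library:

- **Summit-window signal matrices.**  Tag libraries are reduced to 5'
  positions, normalized to a common depth of 10⁷ reads, and averaged over
  `summit ± 50 bp` windows of the merged AML1/AML1-ETO loci, giving a
  loci × libraries matrix of densities (tags/bp).
- **Co-occupancy clustering with a principled choice of k.**  k-means is
  run for `k = 1..k_max` on the data and on column-permuted randomized
  instances; the chosen k maximizes the gap
  `SSE_random(k) − SSE_actual(k)`.  Clusters are relabeled so cluster 1 is
  the N-CoR-high (repressor) class and cluster 2 the H3K4me3-high
  (active) class.
- **Discriminative motif discovery.**  A PWM separating cluster-1
  sequences from the rest is found by simulated annealing on the AUC of
  per-sequence best-site log-odds scores, with Metropolis–Hastings column
  moves; scanning uses exact site p-values from a dynamic-programming
  convolution of the discretized score distribution (threshold p < 10⁻⁴).
- **Genomic-element classification** of each locus into five exclusive
  classes (promoter, exon, intron, TTS-proximal, distal intergenic),
  compared against chromosome/length-matched random and motif-matched
  backgrounds.
- **Expression linkage.**  Probe-level knockdown expression is reduced to
  one probe per gene (largest IQR), fitted gene-wise with a blocked linear
  model (`~0 + block + condition`), and summarized by empirical-Bayes
  moderated t scores (`t = log₂FC / SE`).  Loci map to genes by nearest
  TSS; a gene touched by several clusters is assigned under **cluster-1
  dominance** (any cluster-1 locus makes it a cluster-1 gene).  Cluster
  shifts are tested with Welch t-tests on t-score distributions and
  Fisher's exact association with substantially altered genes
  (log₂FC > 1, p < 0.01).
- **Synthetic data with ground truth.**  `chipsig.simulate` generates a
  genome, gene models, cluster-structured tag libraries (Poisson counts,
  a shared lognormal factor coupling AML1-ETO and N-CoR), planted
  ETS-like motif sites, and blocked two-condition expression — so every
  stage is testable against known truth without any downloads.

## Worked example

`examples/` contains one short script per capability.  Choosing k and
profiling the clusters on a simulated study (`examples/03_signal_and_clusters.py`):

```
signal matrix: 600 loci x 5 libraries
 k  sse_actual  sse_random_mean  sse_random_sd   gap
 1      3000.0           3000.0            0.0   0.0
 2      1984.6           2475.4            3.2 490.8
 3      1331.9           2165.2            9.2 833.3
 4      1174.4           1940.4           15.5 766.0
 ...
chosen k = 3 (gap maximal)

per-cluster mean densities (tags/bp at 1e7 depth):
          AML1  AML1-ETO  N-CoR  p300  H3K4me3
cluster
1         6.26     13.98  12.06  7.11     1.89
2         5.26      3.84   2.94  7.20    13.74
3        11.43      5.77   3.32  7.28     2.64

agreement with planted clusters: 96.0%
```

The SSE gap peaks at the planted k = 3.  Cluster 1 shows the
fusion-protein/co-repressor signature with low H3K4me3, cluster 2 the
active-promoter inverse, and p300 is flat across clusters.  Linking the
clusters to knockdown expression (`examples/06_expression_linkage.py`):

```
263 genes fitted; moderated-t prior: d0 = inf, s0^2 = 0.0668
genes per exclusive cluster (dominance rule): [148, 65, 50]
cluster 1 vs 2 t-score shift: t = 37.2, p = 3.04e-66
cluster 1 vs 3 t-score shift: t = 34.9, p = 2.2e-51
substantially altered genes: 76
cluster 1 vs 2 Fisher association: odds = inf, p = 3.41e-16, table = [[76, 72], [0, 65]]
```

Cluster-1 genes — repressed by the fusion protein in the simulation — are
up-regulated on knockdown: their t scores sit far to the right of the
other clusters and all substantially altered genes fall in cluster 1.

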