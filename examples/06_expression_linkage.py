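"""Linking occupancy clusters to knockdown expression changes.

Probe-level expression is deduplicated to one probe per gene (largest
IQR), fitted with the blocked linear model (block + condition), and
summarized by empirical-Bayes moderated t scores.  Loci map to genes by
nearest TSS; genes touched by several clusters follow the cluster-1
dominance rule.  Cluster-wise t-score shifts and the association between
cluster-1 membership and substantially altered expression are tested.
"""

import numpy as np

from chipsig import expression as ex
from chipsig.simulate import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))

gene_expr = ex.dedup_probes_by_iqr(study.expression)
fit = ex.fit_blocked_de(gene_expr, study.design)
de = ex.moderated_t(fit)
print(f"{len(de)} genes fitted; moderated-t prior: "
      f"d0 = {de.attrs['d0']:.1f}, s0^2 = {de.attrs['s0_2']:.4f}")

locus_gene = ex.assign_locus_to_gene(study.peaks, study.genes)
assignments = ex.assign_gene_cluster(locus_gene, study.truth.locus_cluster)
counts = np.bincount([a.cluster for a in assignments], minlength=4)[1:]
print(f"genes per exclusive cluster (dominance rule): {counts.tolist()}")

groups = ex.t_scores_by_cluster(de, assignments)
for ref in (2, 3):
    stat, p = ex.compare_cluster_shift(
        groups[1], groups[ref], alternative="greater"
    )
    print(f"cluster 1 vs {ref} t-score shift: t = {stat:.1f}, p = {p:.3g}")

altered = ex.substantially_altered(de)  # log2fc > 1 and p < 0.01
print(f"substantially altered genes: {int(altered.sum())}")
for ref in (2, 3):
    odds, p, table = ex.fisher_cluster_association(assignments, altered, ref)
    print(f"cluster 1 vs {ref} Fisher association: "
          f"odds = {odds:.2f}, p = {p:.3g}, table = {table.tolist()}")
# Cluster-1 genes carry the planted positive knockdown shift, so their
# t-score distribution sits to the right of clusters 2 and 3 and they are
# over-represented among the substantially altered genes.
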