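"""Signal matrix, choice of k by randomized SSE, and cluster profiles.

Mean normalized tag densities (tags/bp at 10^7-read depth) are collected
over every locus's summit +/- 50 bp window for all five libraries; k-means
is run for k = 1..8 on the data and on 50 column-permuted randomizations,
and the k maximizing the randomized-minus-actual SSE gap is chosen.
Clusters are then relabeled so cluster 1 is the N-CoR-high (repressor)
class and cluster 2 the H3K4me3-high (active promoter) class.
"""

import numpy as np

from chipsig import clustering, signal
from chipsig.simulate import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
matrix = signal.build_signal_matrix(
    study.peaks, list(study.tag_libraries.values()),
    flank=50, chrom_sizes=study.chrom_sizes,
)
print(f"signal matrix: {matrix.shape[0]} loci x {matrix.shape[1]} libraries")

curve = clustering.select_k(matrix, k_max=8, n_random=50, seed=1)
print(curve.to_frame().round(1).to_string(index=False))
print(f"chosen k = {curve.chosen_k} (gap maximal)")

result = clustering.kmeans_cluster(matrix, curve.chosen_k, seed=1)
result = clustering.semantic_relabel(matrix, result)
profiles = clustering.cluster_profiles(matrix, result.labels)
print("\nper-cluster mean densities (tags/bp at 1e7 depth):")
print(profiles.round(2).to_string())

truth = np.array([study.truth.locus_cluster[p.name] for p in study.peaks])
agreement = float(np.mean(result.labels == truth))
print(f"\nagreement with planted clusters: {100 * agreement:.1f}%")
# Cluster 1 shows the fusion-protein/co-repressor signature with low
# H3K4me3; cluster 2 the inverse; the gap curve peaks at the planted k.
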