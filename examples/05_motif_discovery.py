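"""Discriminative motif discovery, scanning, and per-cluster enrichment.

A PWM separating cluster-1 summit sequences from the rest is found by
simulated annealing on an AUC objective (Metropolis-Hastings column moves
plus occasional register shifts).  The discovered motif is then scanned
across all loci at exact DP p-values, and its per-cluster enrichment is
summarized by the fraction of motif-positive loci and a two-sample KS test
on best-site scores.
"""

import numpy as np

from chipsig import intervals, motifs
from chipsig.simulate import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=1))
truth = study.truth.locus_cluster
windows = [intervals.summit_window(p, 50, study.chrom_sizes)
           for p in study.peaks]
seqs = intervals.extract_sequences(windows, study.genome)
named = [(p.name, s) for p, (_, s) in zip(study.peaks, seqs)]

pos = [s for (n, s) in named if truth[n] == 1]
neg = [s for (n, s) in named if truth[n] != 1]
res = motifs.anneal_discriminative_motif(
    pos, neg, width=10, schedule=(0.01, 0.999, 8000), seed=1
)
print(f"best AUC: {res.best_auc:.3f}  consensus: {res.pwm.consensus}")
corr = motifs.pwm_alignment_correlation(res.pwm, study.config.planted_pwm)
print(f"column correlation with planted ETS-like motif: {corr:.2f}")

hits = motifs.scan_sequences(res.pwm, named, p_threshold=1e-4)
frac = motifs.motif_fraction_by_cluster(hits, truth)
print("fraction of motif-positive loci per cluster:",
      {c: round(f, 3) for c, f in frac.items()})

scores = {n: motifs.best_site_score(res.pwm, s) for n, s in named}
d, p = motifs.ks_overrepresentation(
    [scores[n] for n in scores if truth[n] == 1],
    [scores[n] for n in scores if truth[n] != 1],
)
print(f"KS over-representation in cluster 1: D = {d:.3f}, p = {p:.3g}")
# The discovered consensus matches the planted AGGAAGTG core (possibly
# reverse-complemented or shifted); cluster 1 carries the highest motif
# fraction, mirroring its planted 60% vs 10%/10% site frequency.
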