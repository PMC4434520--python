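"""End-to-end co-occupancy signature analysis.

Composes the modules into the full post-peak-calling workflow: build the
summit-window signal matrix, choose and run k-means, relabel clusters by
their co-occupancy semantics, discover the discriminative motif, scan and
test for its per-cluster enrichment, and link clusters to differential
expression through nearest-TSS assignment and the cluster-1 dominance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering, expression, intervals, motifs, signal
from .simulate import SimStudy


@dataclass
class AnalysisResult:
    signal_matrix: signal.SignalMatrix
    k_curve: clustering.KSelectionCurve | None
    clusters: clustering.ClusteringResult
    profiles: pd.DataFrame
    element_distribution: pd.DataFrame
    correlations: pd.DataFrame
    motif: motifs.PWM
    motif_auc: float
    motif_fractions: dict[int, float]
    ks_stat: float
    ks_p: float
    de: pd.DataFrame
    gene_assignments: list[expression.GeneClusterAssignment]
    shift_tests: dict[str, tuple[float, float]]
    fisher_tests: dict[str, tuple[float, float, np.ndarray]]


def run_analysis(
    study: SimStudy,
    seed: int = 0,
    flank: int = 50,
    k: int | None = None,
    k_max: int = 8,
    n_random: int = 50,
    anneal_steps: int = 20_000,
    motif_width: int = 8,
    scan_p: float = 1e-4,
) -> AnalysisResult:
    """Run the full signature analysis on a (simulated or loaded) study.

    When ``k`` is None the cluster number is chosen by the randomized-SSE
    gap over ``1..k_max``; pass ``k=3`` to fix it.  Problem sizes
    (``n_random``, ``anneal_steps``) default to desk-scale values.
    """
    rng = np.random.default_rng(seed)
    peaks, genes, sizes = study.peaks, study.genes, study.chrom_sizes
    libs = list(study.tag_libraries.values())

    matrix = signal.build_signal_matrix(peaks, libs, flank=flank,
                                        chrom_sizes=sizes)
    correlations = signal.library_correlation(matrix)

    k_curve = None
    if k is None:
        k_curve = clustering.select_k(
            matrix, k_max=k_max, n_random=n_random,
            seed=int(rng.integers(2**31)),
        )
        k = k_curve.chosen_k
    result = clustering.kmeans_cluster(
        matrix, k, seed=int(rng.integers(2**31))
    )
    result = clustering.semantic_relabel(matrix, result)
    profiles = clustering.cluster_profiles(matrix, result.labels)

    bg_random = intervals.sample_random_background(
        [p.interval for p in peaks], sizes, n=len(peaks),
        seed=int(rng.integers(2**31)),
    )
    element_dist = clustering.element_distribution_by_cluster(
        peaks, result.labels, genes, backgrounds={"random": bg_random}
    )

    # discriminative motif: cluster 1 vs clusters 2+3 summit-window sequences
    windows = [intervals.summit_window(p, flank, sizes) for p in peaks]
    seqs = intervals.extract_sequences(windows, study.genome)
    membership = {
        p.name: int(l) for p, l in zip(peaks, result.labels)
    }
    pos_seqs = [s for (_, s), p in zip(seqs, peaks) if membership[p.name] == 1]
    neg_seqs = [s for (_, s), p in zip(seqs, peaks) if membership[p.name] != 1]
    anneal = motifs.anneal_discriminative_motif(
        pos_seqs, neg_seqs, width=motif_width,
        schedule=(0.02, 0.999, anneal_steps),
        seed=int(rng.integers(2**31)),
    )
    pos_best = motifs.best_site_scores(anneal.pwm, pos_seqs)
    neg_best = motifs.best_site_scores(anneal.pwm, neg_seqs)
    ks_stat, ks_p = motifs.ks_overrepresentation(pos_best, neg_best)

    named_seqs = [
        (p.name, s) for p, (_, s) in zip(peaks, seqs)
    ]
    hits = motifs.scan_sequences(anneal.pwm, named_seqs, p_threshold=scan_p)
    fractions = motifs.motif_fraction_by_cluster(hits, membership)

    # expression linkage
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        locus_gene = expression.assign_locus_to_gene(peaks, genes)
    locus_cluster = membership
    assignments = expression.assign_gene_cluster(locus_gene, locus_cluster)
    gene_expr = expression.dedup_probes_by_iqr(study.expression)
    fit = expression.fit_blocked_de(gene_expr, study.design)
    de = expression.moderated_t(fit)
    groups = expression.t_scores_by_cluster(de, assignments)
    shift_tests = {}
    for ref in (2, 3):
        if 1 in groups and ref in groups:
            shift_tests[f"1_vs_{ref}"] = expression.compare_cluster_shift(
                groups[1], groups[ref], alternative="greater"
            )
    altered = expression.substantially_altered(de)
    fisher_tests = {}
    for ref in (2, 3):
        try:
            fisher_tests[f"1_vs_{ref}"] = (
                expression.fisher_cluster_association(
                    assignments, altered, ref
                )
            )
        except ValueError:
            pass

    return AnalysisResult(
        signal_matrix=matrix,
        k_curve=k_curve,
        clusters=result,
        profiles=profiles,
        element_distribution=element_dist,
        correlations=correlations,
        motif=anneal.pwm,
        motif_auc=anneal.best_auc,
        motif_fractions=fractions,
        ks_stat=ks_stat,
        ks_p=ks_p,
        de=de,
        gene_assignments=assignments,
        shift_tests=shift_tests,
        fisher_tests=fisher_tests,
    )
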