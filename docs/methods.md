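# Methods

This note documents the models, numerical choices, and limitations of
`chipsig` in the order of the analysis pipeline.  Conventions first:
coordinates are 0-based half-open (BED); a summit is an absolute 0-based
position; "summit ± f" denotes the `2f+1`-base window `[summit−f,
summit+f+1)`, clipped at chromosome edges (the clipped length is used as
the density denominator).  Strand is ignored for overlap computations and
used only to orient TSS/TTS.

## Signal model

Aligned tags are reduced to single 5' base positions (start for `+`
reads, `end−1` for `−`); no fragment-extension or shift model is applied.
Replicate libraries are pooled by multiset union.  The normalized mean
density of a library over a window is
`count · (10⁷ / total_tags) / window_length` (tags per base at a common
depth of 10⁷), making libraries of different sequencing depth comparable;
the statistic is invariant to uniform duplication of all tags.  Window
counting uses binary search on per-chromosome sorted positions and is
tested against a linear-scan oracle.  A bedGraph alternative computes
coverage-weighted window means rescaled by `10⁷ / declared_total`; the
declared total must come from configuration because coverage alone does
not determine read count.

## Clustering and the choice of k

Before k-means the density matrix is transformed `log2(1 + x)` and each
column standardized (both steps toggleable).  Without this, the
highest-dynamic-range library dominates the Euclidean metric; with it,
each library contributes comparably.  Cluster profiles and all reported
per-cluster means are always on the raw density scale.

k-means uses squared-Euclidean distance, k-means++ seeding, best of
`n_init = 10` starts, 300 iteration cap, relative tolerance 10⁻⁴
(scikit-learn's implementation).  The number of clusters is chosen by
clustering the data and a shared set of randomized instances for each
`k = 1..k_max` (defaults 15 for analysis, 8 in the desk-scale runs) and
maximizing `mean SSE_random(k) − SSE_actual(k)`, ties toward smaller k.
Randomization permutes each column independently across rows: per-library
marginal distributions are preserved exactly while locus-level joint
structure is destroyed.  All randomized instances are clustered with the
same settings as the data, including `n_init`.  The gap rises while added
centroids capture real joint structure and falls once they only chase
marginal dispersion, so it peaks at the true cluster count on separated
data; on structureless data the gap is near zero everywhere.

Cluster indices from k-means are arbitrary, so labels are renamed by
signal semantics: cluster 1 = highest mean co-repressor (N-CoR) density,
cluster 2 = highest mean H3K4me3 among the rest, remaining clusters
ordered by co-repressor mean.  This makes "cluster 1" a stable,
interpretable identity (the repressor-co-occupied signature) and renders
the downstream dominance rule deterministic.

## Genomic-element classification

Five mutually exclusive classes with precedence `promoter > exon >
intron > tts_proximal > distal_intergenic`, evaluated at the locus
midpoint.  A promoter is `TSS ± 2000 bp`; TTS-proximal is the gene 3'
end `± 2000 bp`; both flanks are parameters.  Midpoint classification
(rather than any-overlap) guarantees exactly one label per locus, so
per-cluster fractions sum to 1.  Expected baselines come from two
samplers: random loci matched to the observed chromosome-and-length
distribution with uniform placement, and motif-matched loci centered on
genomic positions whose best PWM site score (either strand) exceeds a
threshold, sampled without replacement.  Both are bit-reproducible under
a fixed seed.

## Discriminative motif discovery

The objective for a candidate PWM is the AUC (Mann–Whitney form, ties
counted half) of per-sequence best-site scores, positives (cluster-1
windows) versus negatives (all other windows).  Site scores are log₂
odds against an i.i.d. background estimated from the pooled input
sequences (uniform available by configuration), with probabilities
regularized as `(p + c)/(1 + 4c)` (pseudocount `c = 10⁻³`); non-ACGT
bases contribute 0.  Best-site scoring maximizes over all windows on both
strands.

Optimization is simulated annealing from a random PWM (columns drawn
flat-Dirichlet).  The main move resamples one uniformly chosen column
from a Dirichlet centered on the current column; the concentration is
drawn log-uniformly from [5, 200] per move, mixing coarse escape moves
with fine refinements.  Column moves alone cannot repair a motif locked
into a shifted register (every intermediate is worse), so with
probability 0.1 the proposal instead shifts the whole matrix by ±1
position, a fresh flat-Dirichlet column entering at the vacated end.
Acceptance is Metropolis: `min(1, exp(ΔAUC / T))`; the Dirichlet column
proposal is treated as symmetric by default, with the exact Hastings
ratio available via `exact_mh`.  The schedule is geometric
(`T0 = 0.01`, factor 0.999/step — AUC differences are of order 10⁻²) and
cyclic: the step budget (default 20,000) is split into 3 anneals that
each reheat to T0, so a run trapped early gets fresh chances to escape
while each cycle ends in a long greedy polish.  The best-AUC PWM ever
visited is returned with a per-step trace.  Default width 10; searching
several widths and keeping the max-AUC motif is a one-line loop.  Scoring
is incremental — when one column changes, all window scores are updated
with a single gather — which is what makes 20,000 evaluations over ~10⁵
windows tractable.

Recovery is measured as the mean per-column Pearson correlation between
the discovered and reference probability matrices after the best
offset/strand alignment (partial overlaps of at least half the narrower
width allowed, so a ±1-register solution with one overhanging noise
column is scored on its matching core).

### Scan p-values

The null distribution of a site score under the background is computed
exactly by dynamic programming: per-position log-odds are discretized to
0.01-bit bins and convolved across positions weighted by background base
probabilities.  Scanning computes each window's binned score on both
strands and reports windows with tail probability `< 10⁻⁴` (FIMO-style).
For widths ≤ 6 the table matches exhaustive enumeration of all 4^w words
to 10⁻¹².  Note that for a width-8 motif the 10⁻⁴ threshold admits only
the top few of the 4⁸ words — effectively exact-consensus matches — so
per-cluster enrichment summaries (fractions of motif-positive loci, KS
test on best-site scores) are the robust downstream statistics, not
per-site recovery of softly sampled planted sites.

## Expression linkage

Probe sets without a gene annotation are excluded; among probes sharing a
gene, the one with the largest interquartile range across samples is
kept (ties to the lexicographically smallest probe id).  Gene-wise
expression is fitted by least squares on the design `~0 + block +
condition` — one indicator per block (transfection batch or time-point)
plus a treatment indicator — so the condition coefficient is the log₂
fold-change adjusted for block effects; with one knockdown/control pair
per block this reduces to the mean of per-block paired differences.

Moderated t statistics shrink per-gene residual variances toward a prior:
`s²_post = (d₀s₀² + df·s²)/(d₀ + df)`, `t = log₂FC/(s_post·SE_unscaled)`
with `d₀ + df` degrees of freedom.  The prior `(d₀, s₀²)` is estimated by
method of moments on log residual variances (digamma/trigamma matching;
trigamma inverted by Newton iteration).  When the observed spread of log
variances does not exceed the χ² sampling spread, `d₀ = ∞` and the common
variance is used — the expected regime for the homoskedastic synthetic
generator; `d₀ = 0` recovers ordinary t.

Each locus is assigned the gene with the nearest TSS to its summit
(absolute distance, ties to the smaller gene id, optional distance
cutoff).  A gene supported by loci from several clusters takes the
minimum cluster label (dominance order 1 > 2 > 3): the repressor-
co-occupied locus is assumed limiting.  The extension of dominance to
clusters 2 over 3 is a determinism choice for genes without cluster-1
loci.  Cluster shifts are compared by Welch's unequal-variance t-test on
the per-cluster t-score distributions (one-sided option for "cluster 1
higher"); "substantially altered" is the signed rule `log₂FC > 1 and
p < 0.01` by default, with an absolute-value variant by flag.  Fisher's
exact test (two-sided, hypergeometric-sum definition) compares cluster 1
against one reference cluster at a time on the 2×2 table {cluster 1,
reference} × {altered, not}; no multiple-testing correction is applied
across the two comparisons.

## Synthetic-data generator

The generator encodes the qualitative structure the analysis is meant to
detect as explicit, parameterized distributions.  Defaults (all
overridable in `SimConfig`): two 6-Mb chromosomes of i.i.d. uniform ACGT;
300 genes with evenly spaced jittered TSSs, random strand, 2–5 exons;
200 loci per cluster, cluster-2 summits within ±1.5 kb of a sampled TSS,
clusters 1 and 3 placed ≥ 10 kb from any TSS by rejection sampling.
In-window tag counts are Poisson with cluster × library means

| cluster | AML1 | AML1-ETO | N-CoR | p300 | H3K4me3 |
|---|---|---|---|---|---|
| 1 (repressor-co-occupied, distal) | 25 | 60 | 50 | 30 | 5 |
| 2 (TSS-proximal, active) | 20 | 15 | 10 | 30 | 60 |
| 3 (AML1-high, distal) | 50 | 25 | 12 | 30 | 8 |

chosen so the three classes span distinct directions of the five-library
space (p300 deliberately flat; cluster 3 distinguished by AML1 rather
than lying on the cluster-1→2 axis, which would make it invisible to any
cluster-number criterion).  AML1-ETO and N-CoR counts share a per-locus
lognormal factor (sd 0.5, mean 1), creating their excess pairwise
correlation beyond what cluster structure induces.  Tag positions are
triangular around the summit; background tags are uniform at 0.02
tags/bp/library.  Motif sites are sampled from a sharp ETS-like 8-mer PWM
(consensus AGGAAGTG, per-position probability 0.85) and planted in a
uniformly chosen window inside summit ± 50 with per-cluster frequencies
(0.6, 0.1, 0.1).  Expression uses 4 blocks with one knockdown/control
pair each, gene baselines N(7, 1), block effects N(0, 0.5), residual sd
0.25, 1–3 probes per gene with constant affinity offsets (sd 0.3) plus
small probe noise (sd 0.05); cluster-1 genes receive a +1 log₂ knockdown
shift by default.  Gene-level truth is derived with the pipeline's own
nearest-TSS and dominance rules so the manifest is consistent with the
emitted files.  All components draw from child generators spawned
deterministically from one master seed.

What the generator does **not** emulate: mappability and GC biases,
fragment-size effects, duplicated reads, overdispersion beyond the
lognormal factor (a negative-binomial option exists via the latent
factor only), motif positional preference within peaks, correlated
probe noise, and any H3K27me3-like mark.  Passing tests therefore show
the algorithms recover planted structure of the stated form, not that
they are robust to every artifact of real sequencing data.

## Problem sizes in tests

The test and acceptance runs use desk-scale sizes chosen to keep the
statistical claims meaningful: 600 loci × 5 libraries with `k_max = 8`
and 50 randomized instances for cluster-number recovery (20 trials);
one planted fixture of 200 positive / 400 negative 101-bp sequences with
a 60%/5% planted 8-mer for motif recovery (10 annealing seeds, 20,000
steps each); 1,500 genes (300/600/600 per cluster) with a 0.8-residual-sd
planted shift for expression recovery, plus 20 null seeds for
calibration.  Exactness checks enumerate all 4^w words for widths ≤ 6 and
all 2×2 tables with margins ≤ 30.

## Known limitations

- The AUC objective uses each sequence's single best site; motifs acting
  through homotypic site clusters would be under-weighted.
- The annealer maximizes empirical AUC on the given sequences; with weak
  planted signal its best-AUC estimate exceeds the population AUC of the
  true motif (optimization bias), so discovered-motif AUCs should be
  validated on held-out sequences when used for inference.
- Gap-based cluster-number selection assumes clusters occupy distinct
  directions after column standardization; nested or collinear classes
  merge.
- Nearest-TSS gene assignment ignores topological domains and enhancer
  skipping; the dominance rule is a deliberate simplification that
  biases multi-locus genes toward cluster 1.
- The moderated-t prior assumes a common residual df across genes (true
  here, where all genes share one design).
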