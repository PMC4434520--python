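"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a multi-library ChIP-seq co-occupancy
study: a random genome with gene models, three planted occupancy clusters
(cluster 1: gene-distal, high fusion-protein/co-repressor signal, low
H3K4me3; cluster 2: TSS-proximal, high H3K4me3; cluster 3: intermediate and
distal), an ETS-like motif planted preferentially in cluster-1 loci, and a
blocked two-condition expression experiment in which cluster-1 target genes
carry a positive knockdown shift.  Every output re-parses through the
package's own readers, and a ground-truth manifest records all planted
structure so recovery can be measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import DesignSpec, assign_gene_cluster, assign_locus_to_gene
from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    write_chrom_sizes,
    write_peaks_narrowpeak,
)
from .motifs import PWM
from .signal import SignalMatrix, TagLibrary, write_tags_bed6

LIBRARIES = ("AML1", "AML1-ETO", "N-CoR", "p300", "H3K4me3")

#: libraries whose in-window counts share a per-locus lognormal latent
#: factor, inducing their excess pairwise correlation
_LATENT_PAIR = ("AML1-ETO", "N-CoR")

_DEFAULT_SIGNAL_MEANS = {
    1: {"AML1": 25.0, "AML1-ETO": 60.0, "N-CoR": 50.0, "p300": 30.0,
        "H3K4me3": 5.0},
    2: {"AML1": 20.0, "AML1-ETO": 15.0, "N-CoR": 10.0, "p300": 30.0,
        "H3K4me3": 60.0},
    3: {"AML1": 50.0, "AML1-ETO": 25.0, "N-CoR": 12.0, "p300": 30.0,
        "H3K4me3": 8.0},
}


@dataclass
class ExpressionConfig:
    """Blocked two-condition expression simulation parameters (log2 units)."""

    n_blocks: int = 4
    delta: float = 1.0  # knockdown shift for cluster-1 genes
    residual_sd: float = 0.25
    batch_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    probe_offset_sd: float = 0.3
    probe_noise_sd: float = 0.05
    max_probes: int = 3


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 6_000_000
    n_genes: int = 300
    n_loci_per_cluster: tuple[int, int, int] = (200, 200, 200)
    signal_means: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            c: dict(v) for c, v in _DEFAULT_SIGNAL_MEANS.items()
        }
    )
    background_rate: float = 0.02  # tags per base, per library
    latent_sd: float = 0.5  # lognormal sd of the shared AML1-ETO/N-CoR factor
    motif_plant_freq: tuple[float, float, float] = (0.6, 0.1, 0.1)
    planted_consensus: str = "AGGAAGTG"  # ETS-like core
    planted_match_prob: float = 0.85
    peak_halfwidth: int = 150
    summit_flank: int = 50
    promoter_jitter: int = 1500
    min_tss_distance: int = 10_000
    aml1_shared_fraction: float = 0.71
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    @property
    def planted_pwm(self) -> PWM:
        return PWM.from_consensus(
            self.planted_consensus, self.planted_match_prob
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["n_loci_per_cluster"] = list(d["n_loci_per_cluster"])
        d["motif_plant_freq"] = list(d["motif_plant_freq"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["expression"] = ExpressionConfig(**d.get("expression", {}))
        d["n_loci_per_cluster"] = tuple(d["n_loci_per_cluster"])
        d["motif_plant_freq"] = tuple(d["motif_plant_freq"])
        d["signal_means"] = {
            int(c): {k: float(v) for k, v in row.items()}
            for c, row in d["signal_means"].items()
        }
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    locus_cluster: dict[str, int] = field(default_factory=dict)
    motif_offsets: dict[str, list[int]] = field(default_factory=dict)
    gene_cluster: dict[str, int] = field(default_factory=dict)
    gene_shift: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            locus_cluster={k: int(v) for k, v in d["locus_cluster"].items()},
            motif_offsets={
                k: [int(x) for x in v] for k, v in d["motif_offsets"].items()
            },
            gene_cluster={k: int(v) for k, v in d["gene_cluster"].items()},
            gene_shift={k: float(v) for k, v in d["gene_shift"].items()},
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(cfg: SimConfig) -> tuple[dict[str, str], dict[str, int]]:
    """I.i.d. uniform-ACGT genome and its chromosome-size table."""
    if cfg.chrom_length < 10_000:
        raise ValueError("chromosomes must be >= 10 kb")
    rng = _child_rngs(cfg.seed, 1)[0]
    genome = {}
    sizes = {}
    for i in range(cfg.n_chrom):
        name = f"chr{i + 1}"
        idx = rng.integers(0, 4, size=cfg.chrom_length)
        genome[name] = _BASES[idx].tobytes().decode("ascii")
        sizes[name] = cfg.chrom_length
    return genome, sizes


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def make_genes(cfg: SimConfig, sizes: dict[str, int]) -> list[GeneModel]:
    """Genes with roughly evenly spaced, jittered TSSs and 2-5 exons."""
    rng = _child_rngs(cfg.seed, 2)[1]
    per_chrom = cfg.n_genes // cfg.n_chrom
    if per_chrom < 1:
        raise ValueError("need at least one gene per chromosome")
    genes: list[GeneModel] = []
    gid = 0
    for chrom, size in sizes.items():
        spacing = size // (per_chrom + 1)
        if spacing < 20_000:
            raise ValueError("genome too crowded for distal locus placement")
        for i in range(per_chrom):
            center = (i + 1) * spacing
            center += int(rng.integers(-spacing // 10, spacing // 10 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            span_len = int(rng.integers(2000, 8001))
            if strand == "+":
                start = center
                end = min(center + span_len, size)
            else:
                end = center + 1
                start = max(end - span_len, 0)
            tss = start if strand == "+" else end - 1
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(
                rng.choice(
                    np.arange(start + 1, end), size=2 * n_exons - 2,
                    replace=False,
                )
            )
            bounds = [start, *cuts.tolist(), end]
            exons = [
                GenomicInterval(chrom, bounds[2 * j], bounds[2 * j + 1])
                for j in range(n_exons)
            ]
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gid:04d}", chrom=chrom, strand=strand,
                    tss=tss, exons=exons,
                )
            )
            gid += 1
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texon_starts\texon_ends\n")
        for g in genes:
            starts = ",".join(str(e.start) for e in g.exons)
            ends = ",".join(str(e.end) for e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{starts}\t"
                f"{ends}\n"
            )


def read_gene_table(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: missing gene table header")
        for line in fh:
            gid, chrom, strand, tss, starts, ends = line.split()
            exons = [
                GenomicInterval(chrom, int(s), int(e))
                for s, e in zip(starts.split(","), ends.split(","))
            ]
            genes.append(GeneModel(gid, chrom, strand, int(tss), exons))
    return genes


# ---------------------------------------------------------------------------
# Locus placement and tag simulation
# ---------------------------------------------------------------------------


def place_cluster_loci(
    cfg: SimConfig, genes: list[GeneModel], sizes: dict[str, int]
) -> tuple[list[Peak], GroundTruth]:
    """Place summits per cluster: cluster 2 at promoters, 1 and 3 distal."""
    rng = _child_rngs(cfg.seed, 3)[2]
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {
        c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()
    }
    chroms = list(sizes)
    hw = cfg.peak_halfwidth
    peaks: list[Peak] = []
    truth = GroundTruth()
    idx = 0

    def distal_summit() -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(hw, sizes[chrom] - hw - 1))
            tss = tss_by_chrom.get(chrom)
            if tss is None or tss.size == 0:
                return chrom, pos
            i = int(np.searchsorted(tss, pos))
            near = min(
                abs(pos - int(tss[j]))
                for j in (i - 1, i) if 0 <= j < tss.size
            )
            if near >= cfg.min_tss_distance:
                return chrom, pos
        raise RuntimeError("could not place a distal locus; genome too dense")

    for cluster, count in zip((1, 2, 3), cfg.n_loci_per_cluster):
        for _ in range(count):
            if cluster == 2:
                g = genes[int(rng.integers(len(genes)))]
                jit = int(
                    rng.integers(-cfg.promoter_jitter, cfg.promoter_jitter + 1)
                )
                summit = min(
                    max(g.tss + jit, hw), sizes[g.chrom] - hw - 1
                )
                chrom = g.chrom
            else:
                chrom, summit = distal_summit()
            name = f"locus_{idx:04d}"
            idx += 1
            peaks.append(
                Peak(
                    GenomicInterval(chrom, summit - hw, summit + hw + 1),
                    summit,
                    float(rng.uniform(20.0, 60.0)),
                    name,
                )
            )
            truth.locus_cluster[name] = cluster
    peaks = sorted(peaks, key=lambda p: (p.chrom, p.interval.start))
    return peaks, truth


def simulate_tags(
    cfg: SimConfig,
    peaks: list[Peak],
    truth: GroundTruth,
    sizes: dict[str, int],
) -> dict[str, TagLibrary]:
    """Poisson in-window tag counts plus uniform genome-wide background.

    Cluster x library means follow the configured signature (cluster 1
    fusion-protein/co-repressor high, cluster 2 H3K4me3 high, p300 flat);
    AML1-ETO and N-CoR share a per-locus lognormal factor so their signals
    correlate beyond what cluster structure alone induces.  Tag positions
    are triangular around the summit.
    """
    rng = _child_rngs(cfg.seed, 4)[3]
    positions: dict[str, dict[str, list[np.ndarray]]] = {
        lib: {c: [] for c in sizes} for lib in LIBRARIES
    }
    # per-locus shared latent factor, mean 1
    latent = {
        p.name: float(
            np.exp(rng.normal(-cfg.latent_sd**2 / 2.0, cfg.latent_sd))
        )
        for p in peaks
    }
    for p in peaks:
        cluster = truth.locus_cluster[p.name]
        means = cfg.signal_means[cluster]
        for lib in LIBRARIES:
            mean = means[lib]
            if lib in _LATENT_PAIR:
                mean = mean * latent[p.name]
            count = int(rng.poisson(mean))
            if count == 0:
                continue
            offs = rng.triangular(
                -cfg.peak_halfwidth, 0, cfg.peak_halfwidth, size=count
            )
            pos = np.clip(
                np.round(p.summit + offs).astype(np.int64),
                0,
                sizes[p.chrom] - 1,
            )
            positions[lib][p.chrom].append(pos)
    for lib in LIBRARIES:
        for chrom, size in sizes.items():
            n_bg = int(rng.poisson(cfg.background_rate * size))
            if n_bg:
                positions[lib][chrom].append(
                    rng.integers(0, size, size=n_bg)
                )
    libs = {}
    for lib in LIBRARIES:
        merged = {
            chrom: np.concatenate(parts)
            for chrom, parts in positions[lib].items()
            if parts
        }
        libs[lib] = TagLibrary.from_positions(lib, merged)
    return libs


def plant_motifs(
    cfg: SimConfig,
    genome: dict[str, str],
    peaks: list[Peak],
    truth: GroundTruth,
) -> dict[str, str]:
    """Insert PWM-sampled sites into summit windows with per-cluster rates.

    A planted site replaces a uniformly chosen window inside the locus's
    ``summit +/- summit_flank`` region; absolute genomic offsets are
    recorded in the truth manifest.  Returns the modified genome.
    """
    rng = _child_rngs(cfg.seed, 5)[4]
    pwm = cfg.planted_pwm
    w = pwm.width
    if w > 2 * cfg.summit_flank + 1:
        raise ValueError("planted motif wider than the summit window")
    buffers = {c: bytearray(s, "ascii") for c, s in genome.items()}
    freq = cfg.motif_plant_freq
    for p in peaks:
        cluster = truth.locus_cluster[p.name]
        if rng.random() >= freq[cluster - 1]:
            continue
        lo = max(p.summit - cfg.summit_flank, 0)
        hi = min(p.summit + cfg.summit_flank + 1, len(buffers[p.chrom]))
        if hi - lo < w:
            continue
        start = int(rng.integers(lo, hi - w + 1))
        site = pwm.sample_site(rng)
        buffers[p.chrom][start:start + w] = site.encode("ascii")
        truth.motif_offsets.setdefault(p.name, []).append(start)
    return {c: b.decode("ascii") for c, b in buffers.items()}


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: SimConfig,
    gene_clusters: dict[str, int],
    seed_offset: int = 0,
):
    """Probe-level blocked two-condition expression with a cluster-1 shift.

    Each gene gets 1-3 probes; a probe's log2 value is the gene baseline
    plus a block (batch) effect, the knockdown shift ``delta`` for cluster-1
    genes, residual noise, a constant probe affinity offset, and small
    probe-level noise.  Every block contains one knockdown and one control
    sample.  Returns ``(probe_table, design, shifts)``.
    """
    ex = cfg.expression
    if ex.n_blocks < 2:
        raise ValueError("need >= 2 blocks")
    rng = _child_rngs(cfg.seed + seed_offset, 6)[5]
    samples, condition, block = [], [], []
    for b in range(1, ex.n_blocks + 1):
        for cond in ("knockdown", "control"):
            samples.append(f"{cond[:3]}_b{b}")
            condition.append(cond)
            block.append(f"b{b}")
    design = DesignSpec(samples, condition, block,
                        treatment_level="knockdown")
    block_eff = {
        b: float(rng.normal(0.0, ex.batch_sd)) for b in design.blocks
    }
    rows = []
    shifts: dict[str, float] = {}
    for gene in sorted(gene_clusters):
        delta_g = ex.delta if gene_clusters[gene] == 1 else 0.0
        shifts[gene] = delta_g
        baseline = float(rng.normal(ex.baseline_mean, ex.baseline_sd))
        gene_vals = np.array(
            [
                baseline
                + block_eff[b]
                + (delta_g if c == "knockdown" else 0.0)
                + float(rng.normal(0.0, ex.residual_sd))
                for c, b in zip(condition, block)
            ]
        )
        n_probes = int(rng.integers(1, ex.max_probes + 1))
        for j in range(n_probes):
            offset = float(rng.normal(0.0, ex.probe_offset_sd))
            vals = gene_vals + offset + rng.normal(
                0.0, ex.probe_noise_sd, size=gene_vals.size
            )
            rows.append([f"{gene}_p{j}", gene, *vals.tolist()])
    probe_df = pd.DataFrame(rows, columns=["probe_id", "gene_id", *samples])
    return probe_df, design, shifts


# ---------------------------------------------------------------------------
# Convenience matrices and the full-study bundle
# ---------------------------------------------------------------------------


def make_blob_matrix(
    n_loci: int,
    k: int,
    n_libraries: int = 5,
    seed: int = 0,
    separation: float = 3.0,
    noise_sd: float = 0.3,
    base: float = 3.0,
) -> tuple[SignalMatrix, np.ndarray]:
    """Well-separated k-cluster signal matrix with known labels.

    Cluster centers are axis-aligned in log2-density space; densities are
    mapped back through ``2**x - 1`` so the matrix is a valid non-negative
    density table.  Used to test cluster-number selection.
    """
    if k > n_libraries:
        raise ValueError("k must be <= n_libraries for axis-aligned centers")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, k + 1), int(np.ceil(n_loci / k)))[:n_loci]
    rng.shuffle(labels)
    centers = np.full((k, n_libraries), base)
    for c in range(k):
        centers[c, c] += separation
    x = centers[labels - 1] + rng.normal(0, noise_sd,
                                         size=(n_loci, n_libraries))
    dens = np.maximum(2.0**x - 1.0, 0.0)
    matrix = SignalMatrix(
        locus_ids=[f"locus_{i:04d}" for i in range(n_loci)],
        library_names=[f"lib_{j + 1}" for j in range(n_libraries)],
        values=dens,
    )
    return matrix, labels


@dataclass
class SimStudy:
    """All inputs of one simulated study plus its ground truth."""

    config: SimConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    peak_sets: dict[str, list[Peak]]
    tag_libraries: dict[str, TagLibrary]
    expression: object  # probe-level DataFrame
    design: DesignSpec
    truth: GroundTruth


def simulate_study(cfg: SimConfig, outdir=None) -> SimStudy:
    """Generate every pipeline input (optionally written to ``outdir``)."""
    genome, sizes = make_genome(cfg)
    genes = make_genes(cfg, sizes)
    peaks, truth = place_cluster_loci(cfg, genes, sizes)
    tag_libs = simulate_tags(cfg, peaks, truth, sizes)
    genome = plant_motifs(cfg, genome, peaks, truth)

    # per-library peak sets: the fusion-protein library carries every locus;
    # the AML1 library shares a configurable fraction plus unique distal peaks
    rng = _child_rngs(cfg.seed, 7)[6]
    n = len(peaks)
    n_shared = int(round(cfg.aml1_shared_fraction * n))
    shared_idx = rng.choice(n, size=n_shared, replace=False)
    aml1_peaks = []
    hw = cfg.peak_halfwidth
    for i in sorted(int(j) for j in shared_idx):
        p = peaks[i]
        jit = int(rng.integers(-20, 21))
        summit = min(max(p.summit + jit, hw), sizes[p.chrom] - hw - 1)
        aml1_peaks.append(
            Peak(
                GenomicInterval(p.chrom, summit - hw, summit + hw + 1),
                summit, p.score, f"aml1_{p.name}",
            )
        )
    chroms = list(sizes)
    for u in range(n - n_shared):
        chrom = chroms[int(rng.integers(len(chroms)))]
        summit = int(rng.integers(hw, sizes[chrom] - hw - 1))
        aml1_peaks.append(
            Peak(
                GenomicInterval(chrom, summit - hw, summit + hw + 1),
                summit, float(rng.uniform(20, 60)), f"aml1_unique_{u:04d}",
            )
        )
    peak_sets = {"AML1-ETO": peaks, "AML1": sorted(
        aml1_peaks, key=lambda p: (p.chrom, p.interval.start)
    )}

    # gene-level truth via the pipeline's own proximity + dominance rules
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        locus_gene = assign_locus_to_gene(peaks, genes)
    assignments = assign_gene_cluster(
        locus_gene, truth.locus_cluster
    )
    truth.gene_cluster = {a.gene_id: a.cluster for a in assignments}
    expr, design, shifts = simulate_expression(cfg, truth.gene_cluster)
    truth.gene_shift = shifts

    study = SimStudy(
        config=cfg, genome=genome, chrom_sizes=sizes, genes=genes,
        peaks=peaks, peak_sets=peak_sets, tag_libraries=tag_libs,
        expression=expr, design=design, truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_chrom_sizes(sizes, outdir / "genome.chrom.sizes")
        write_gene_table(genes, outdir / "genes.tsv")
        write_peaks_narrowpeak(peaks, outdir / "loci.narrowPeak")
        for lib, pk in peak_sets.items():
            write_peaks_narrowpeak(
                pk, outdir / f"peaks_{lib}.narrowPeak"
            )
        for lib, tl in tag_libs.items():
            write_tags_bed6(tl, outdir / f"tags_{lib}.bed")
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        design.to_frame().to_csv(outdir / "design.tsv", sep="\t", index=False)
        truth.to_json(outdir / "truth.json")
        cfg.to_yaml(outdir / "config.yaml")
    return study
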