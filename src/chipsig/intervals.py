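"""Genomic intervals, peaks, standard-format IO, and element classification.

Coordinates are 0-based half-open throughout (BED convention); a peak summit
is an absolute 0-based position.  A "summit window" of flank ``f`` is the
``2f + 1``-base interval ``[summit - f, summit + f + 1)``, clipped to the
chromosome when sizes are known.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STRANDS = {"+", "-", "."}

ELEMENT_CLASSES = (
    "promoter",
    "exon",
    "intron",
    "tts_proximal",
    "distal_intergenic",
)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called enrichment region with its summit and significance score."""

    interval: GenomicInterval
    summit: int
    score: float  # -log10 p-value of enrichment
    name: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) of {self.name}"
            )
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"exons of {self.gene_id} overlap or are unsorted"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tts(self) -> int:
        """3' end of the gene span (transcription termination side)."""
        span = self.span
        return span.end - 1 if self.strand == "+" else span.start


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_peaks(path) -> list[Peak]:
    """Read peaks from a narrowPeak (10-column) or BED file.

    For narrowPeak input the summit is ``start + col10`` and the score is
    the -log10 p-value in column 8; a summit offset of -1 (summit unknown)
    falls back to the interval midpoint.  For plain BED the midpoint is
    used and the score column (5) is taken when present.
    """
    peaks: list[Peak] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
                if len(parts) >= 10:
                    score = float(parts[7])
                    offset = int(parts[9])
                    summit = (
                        (start + end) // 2 if offset == -1 else start + offset
                    )
                else:
                    score = float(parts[4]) if len(parts) > 4 else 0.0
                    summit = (start + end) // 2
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end), summit,
                         max(score, 0.0), name)
                )
            except (ValueError, IndexError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ValueError(
            f"malformed peak lines in {path}:\n" + "\n".join(errors)
        )
    return sorted(peaks, key=lambda p: (p.chrom, p.interval.start))


def write_peaks_narrowpeak(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\t0\t"
                f"{p.score:g}\t-1\t{p.summit - iv.start}\n"
            )


def write_bed6(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bed6(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            p = line.split()
            strand = p[5] if len(p) > 5 else "."
            out.append(GenomicInterval(p[0], int(p[1]), int(p[2]), strand))
    return out


# ---------------------------------------------------------------------------
# Window arithmetic
# ---------------------------------------------------------------------------


def summit_window(
    peak: Peak, flank: int, chrom_sizes: Mapping[str, int] | None = None
) -> GenomicInterval:
    """Interval ``[summit - flank, summit + flank + 1)`` around the summit.

    Clipped to ``[0, chrom_size)`` when sizes are given.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(peak.summit - flank, 0)
    end = peak.summit + flank + 1
    if chrom_sizes is not None and peak.chrom in chrom_sizes:
        end = min(end, chrom_sizes[peak.chrom])
    return GenomicInterval(peak.chrom, start, end)


def merge_overlapping(
    intervals: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Union of intervals: sorted, pairwise non-overlapping output.

    Abutting half-open intervals (``end == start``) are NOT merged, matching
    the strict-overlap convention used for summit windows.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda x: (x.chrom, x.start, x.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start < last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, iv.end, last.strand
                )
        else:
            merged.append(iv)
    return merged


def overlap_fraction(
    set_a: list[Peak],
    set_b: list[Peak],
    flank: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[float, list[tuple[str, str]]]:
    """Fraction of ``set_a`` peaks whose summit window hits one of ``set_b``.

    Two peaks co-occur when their ``summit +/- flank`` windows intersect.
    Returns the (asymmetric) fraction and the matched ``(name_a, name_b)``
    pairs.
    """
    if not set_a:
        raise ValueError("overlap fraction undefined for empty set_a")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for p in set_b:
        w = summit_window(p, flank, chrom_sizes)
        by_chrom.setdefault(p.chrom, []).append((w.start, w.end, p.name))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    pairs: list[tuple[str, str]] = []
    hit = 0
    for p in set_a:
        w = summit_window(p, flank, chrom_sizes)
        entries = by_chrom.get(p.chrom, [])
        matched = [
            name for (s, e, name) in entries if s < w.end and w.start < e
        ]
        if matched:
            hit += 1
            pairs.extend((p.name, m) for m in matched)
    return hit / len(set_a), pairs


# ---------------------------------------------------------------------------
# Genomic-element classification
# ---------------------------------------------------------------------------


class GeneIndex:
    """Per-chromosome lookup structures for element classification."""

    def __init__(self, genes: list[GeneModel],
                 promoter_flank: int = 2000, tts_flank: int = 2000):
        self.promoter_flank = promoter_flank
        self.tts_flank = tts_flank
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)

    def classify(self, position: int, chrom: str) -> str:
        genes = self.by_chrom.get(chrom)
        if genes is None:
            return "distal_intergenic"
        pf, tf = self.promoter_flank, self.tts_flank
        in_exon = in_intron = near_tts = False
        for g in genes:
            if abs(position - g.tss) <= pf:
                return "promoter"
            if g.exons:
                span = g.span
                if span.start <= position < span.end:
                    if any(
                        e.start <= position < e.end for e in g.exons
                    ):
                        in_exon = True
                    else:
                        in_intron = True
                if abs(position - g.tts) <= tf:
                    near_tts = True
        if in_exon:
            return "exon"
        if in_intron:
            return "intron"
        if near_tts:
            return "tts_proximal"
        return "distal_intergenic"


def classify_element(
    locus: GenomicInterval,
    genes: list[GeneModel] | GeneIndex,
    promoter_flank: int = 2000,
    tts_flank: int = 2000,
) -> str:
    """Assign a locus one of five mutually exclusive element classes.

    The locus midpoint is tested against all genes on its chromosome with
    precedence ``promoter > exon > intron > tts_proximal >
    distal_intergenic``; midpoint classification guarantees exactly one
    label per locus.  A promoter is ``TSS +/- promoter_flank``; the
    tts_proximal window is the gene 3' end ``+/- tts_flank``.
    """
    index = (
        genes
        if isinstance(genes, GeneIndex)
        else GeneIndex(genes, promoter_flank, tts_flank)
    )
    if locus.chrom not in index.by_chrom:
        warnings.warn(
            f"chromosome {locus.chrom} absent from gene annotation; "
            "classifying as distal_intergenic",
            stacklevel=2,
        )
    return index.classify(locus.midpoint, locus.chrom)


def element_distribution(
    loci: list[GenomicInterval],
    genes: list[GeneModel] | GeneIndex,
    promoter_flank: int = 2000,
    tts_flank: int = 2000,
) -> dict[str, float]:
    """Fraction of loci in each of the five element classes (sums to 1)."""
    if not loci:
        raise ValueError("no loci to classify")
    index = (
        genes
        if isinstance(genes, GeneIndex)
        else GeneIndex(genes, promoter_flank, tts_flank)
    )
    counts = dict.fromkeys(ELEMENT_CLASSES, 0)
    for locus in loci:
        counts[index.classify(locus.midpoint, locus.chrom)] += 1
    n = len(loci)
    return {c: counts[c] / n for c in ELEMENT_CLASSES}


# ---------------------------------------------------------------------------
# Background sampling and sequence extraction
# ---------------------------------------------------------------------------


def sample_random_background(
    loci: list[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n: int,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Random loci matching the input chromosome and length distribution.

    Each sample copies the (chromosome, length) of an input locus drawn
    uniformly with replacement and is placed uniformly on that chromosome.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[GenomicInterval] = []
    picks = rng.integers(len(loci), size=n)
    for i in picks:
        src = loci[int(i)]
        size = chrom_sizes[src.chrom]
        if size < src.length:
            raise ValueError(
                f"chromosome {src.chrom} shorter than locus length "
                f"{src.length}"
            )
        start = int(rng.integers(size - src.length + 1))
        out.append(GenomicInterval(src.chrom, start, start + src.length))
    return out


def _genome_items(genome) -> list[tuple[str, str]]:
    """Normalize a genome (dict of str, or pyfaidx.Fasta) to (name, seq)."""
    if isinstance(genome, Mapping):
        return [(c, str(s)) for c, s in genome.items()]
    return [(rec.name, str(rec[:])) for rec in genome]


def sample_motif_matched_background(
    pwm,
    genome,
    n: int,
    score_threshold: float,
    seed: int = 0,
    locus_length: int = 101,
) -> list[GenomicInterval]:
    """Loci centered on genomic positions whose site score beats a threshold.

    The genome is scanned on both strands with the PWM; window positions
    with log-odds >= ``score_threshold`` are candidate centers, from which
    ``n`` are sampled without replacement.  Candidate centers are the
    midpoint of the matching site.
    """
    from . import motifs

    if n < 1:
        raise ValueError("n must be >= 1")
    candidates: list[tuple[str, int]] = []
    w = pwm.width
    for chrom, seq in _genome_items(genome):
        if len(seq) < w:
            continue
        fwd, rev = motifs.window_scores(pwm, seq.upper())
        ok = np.nonzero(np.maximum(fwd, rev) >= score_threshold)[0]
        candidates.extend((chrom, int(i) + w // 2) for i in ok)
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} positions reach score "
            f"{score_threshold}; cannot sample {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    half = locus_length // 2
    out = []
    for i in sorted(int(c) for c in chosen):
        chrom, center = candidates[i]
        start = max(center - half, 0)
        out.append(GenomicInterval(chrom, start, start + locus_length))
    return out


def extract_sequences(
    loci: list[GenomicInterval], genome
) -> list[tuple[str, str]]:
    """Uppercase sequences of loci; ids are ``chrom:start-end``.

    ``genome`` may be a mapping of chromosome name to sequence string or a
    ``pyfaidx.Fasta``.
    """
    if isinstance(genome, Mapping):
        lookup = genome
    else:
        lookup = {rec.name: rec for rec in genome}
    out = []
    for iv in loci:
        if iv.chrom not in lookup:
            raise KeyError(f"chromosome {iv.chrom} missing from genome")
        chrom_seq = lookup[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(f"locus {iv.id} out of chromosome bounds")
        seq = str(chrom_seq[iv.start:iv.end]).upper()
        out.append((iv.id, seq))
    return out
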