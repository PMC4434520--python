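"""Tag libraries, depth normalization, and summit-window signal matrices.

A tag library reduces each aligned read to its single 5' base position.
Densities are reported in tags per base after scaling the library to a
common depth of 10^7 tags, so libraries of different sequencing depth are
directly comparable.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, summit_window

SCALE_REFERENCE = 10_000_000


@dataclass
class TagLibrary:
    """Aligned-tag positions for one ChIP library, sorted per chromosome."""

    name: str
    tags: dict[str, np.ndarray] = field(default_factory=dict)
    total_tags: int = 0

    @classmethod
    def from_positions(
        cls, name: str, positions: Mapping[str, np.ndarray]
    ) -> "TagLibrary":
        tags = {
            chrom: np.sort(np.asarray(pos, dtype=np.int64))
            for chrom, pos in positions.items()
        }
        total = int(sum(len(p) for p in tags.values()))
        return cls(name=name, tags=tags, total_tags=total)

    def count_in(self, window: GenomicInterval) -> int:
        pos = self.tags.get(window.chrom)
        if pos is None:
            return 0
        lo = np.searchsorted(pos, window.start, side="left")
        hi = np.searchsorted(pos, window.end, side="left")
        return int(hi - lo)


def load_tags(path, name: str) -> TagLibrary:
    """Read one tag per BED6 line; position is the 5' base.

    For a ``+`` strand tag the 5' base is the interval start; for ``-`` it
    is ``end - 1``.
    """
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                strand = parts[5]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            if strand == "+":
                pos = start
            elif strand == "-":
                pos = end - 1
            else:
                raise ValueError(
                    f"{path} line {lineno}: unknown strand {strand!r}"
                )
            positions.setdefault(chrom, []).append(pos)
    return TagLibrary.from_positions(name, {
        c: np.array(p, dtype=np.int64) for c, p in positions.items()
    })


def write_tags_bed6(lib: TagLibrary, path, read_length: int = 36) -> None:
    """Write tags as plus-strand BED6 reads starting at each tag position."""
    with open(path, "w") as fh:
        for chrom in sorted(lib.tags):
            for pos in lib.tags[chrom]:
                fh.write(
                    f"{chrom}\t{pos}\t{pos + read_length}\t{lib.name}\t0\t+\n"
                )


def pool_libraries(a: TagLibrary, b: TagLibrary,
                   name: str | None = None) -> TagLibrary:
    """Union of two replicate libraries (tag multisets concatenated)."""
    chroms = set(a.tags) | set(b.tags)
    merged = {}
    for chrom in chroms:
        parts = [t for t in (a.tags.get(chrom), b.tags.get(chrom))
                 if t is not None]
        merged[chrom] = np.sort(np.concatenate(parts))
    return TagLibrary.from_positions(name or a.name, merged)


def normalized_mean_density(
    lib: TagLibrary, window: GenomicInterval
) -> float:
    """Mean tags/base in the window at a normalized depth of 10^7 tags.

    ``count * (10^7 / total_tags) / window_length``.
    """
    if lib.total_tags <= 0:
        raise ValueError(f"library {lib.name} has zero depth")
    count = lib.count_in(window)
    return count * (SCALE_REFERENCE / lib.total_tags) / window.length


@dataclass
class SignalMatrix:
    """Loci x libraries table of normalized mean read densities."""

    locus_ids: list[str]
    library_names: list[str]
    values: np.ndarray
    scale_reference: int = SCALE_REFERENCE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.locus_ids), len(self.library_names)):
            raise ValueError("matrix dimensions inconsistent with id lists")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.locus_ids, columns=self.library_names
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "locus_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            locus_ids=[str(i) for i in df.index],
            library_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


def build_signal_matrix(
    loci: list[Peak],
    libs: list[TagLibrary],
    flank: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> SignalMatrix:
    """Normalized mean density of every library over every summit window.

    Windows are ``summit +/- flank`` (101 bp at the default flank of 50);
    windows clipped at chromosome edges use the clipped length as the
    denominator.
    """
    if not loci or not libs:
        raise ValueError("loci and libs must both be non-empty")
    values = np.zeros((len(loci), len(libs)))
    for i, peak in enumerate(loci):
        window = summit_window(peak, flank, chrom_sizes)
        for j, lib in enumerate(libs):
            values[i, j] = normalized_mean_density(lib, window)
    return SignalMatrix(
        locus_ids=[p.name for p in loci],
        library_names=[lib.name for lib in libs],
        values=values,
    )


def library_correlation(matrix: SignalMatrix) -> pd.DataFrame:
    """Pearson correlation between every pair of library columns.

    Zero-variance columns yield NaN entries and a warning rather than a
    silent zero.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 loci to correlate libraries")
    stds = matrix.values.std(axis=0)
    flat = [matrix.library_names[j] for j in np.nonzero(stds == 0)[0]]
    if flat:
        warnings.warn(
            f"zero-variance libraries {flat}: correlations undefined (NaN)",
            stacklevel=2,
        )
    df = matrix.to_frame().corr(method="pearson")
    np.fill_diagonal(df.values, 1.0)
    for name in flat:
        df.loc[name, :] = np.nan
        df.loc[:, name] = np.nan
        df.loc[name, name] = np.nan
    return df


# ---------------------------------------------------------------------------
# bedGraph coverage alternative
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base coverage from a bedGraph, with a declared sequencing depth.

    The declared total cannot be recovered from coverage alone, so it must
    be supplied (e.g. from run configuration).
    """

    name: str
    declared_total: int
    # per chrom: (starts, ends, values), sorted, non-overlapping
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def mean_density(self, window: GenomicInterval) -> float:
        """Coverage-weighted mean over the window, scaled to 10^7 depth."""
        if self.declared_total <= 0:
            raise ValueError("declared_total must be positive")
        seg = self.segments.get(window.chrom)
        total = 0.0
        if seg is not None:
            starts, ends, vals = seg
            lo = np.searchsorted(ends, window.start, side="right")
            hi = np.searchsorted(starts, window.end, side="left")
            for k in range(lo, hi):
                ov = min(int(ends[k]), window.end) - max(
                    int(starts[k]), window.start
                )
                if ov > 0:
                    total += ov * float(vals[k])
        return (total / window.length) * (
            SCALE_REFERENCE / self.declared_total
        )


def load_bedgraph(path, name: str, declared_total: int) -> CoverageTrack:
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split()[:4]
            per_chrom.setdefault(chrom, []).append(
                (int(start), int(end), float(value))
            )
    segments = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        vals = np.array([r[2] for r in rows])
        segments[chrom] = (starts, ends, vals)
    return CoverageTrack(name=name, declared_total=declared_total,
                         segments=segments)
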