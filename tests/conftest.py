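import numpy as np
import pytest

from chipsig.intervals import GenomicInterval, Peak
from chipsig.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study shared across tests (read-only)."""
    cfg = SimConfig(
        seed=7,
        n_chrom=2,
        chrom_length=1_500_000,
        n_genes=60,
        n_loci_per_cluster=(60, 60, 60),
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """A full-size default-configuration study (read-only)."""
    return simulate_study(SimConfig(seed=11))


def random_peaks(rng, n, chroms=("chr1", "chr2"), size=100_000):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        summit = int(rng.integers(200, size - 200))
        half = int(rng.integers(50, 150))
        peaks.append(
            Peak(
                GenomicInterval(chrom, summit - half, summit + half + 1),
                summit,
                float(rng.uniform(0, 50)),
                f"p{i}",
            )
        )
    return peaks


def random_intervals(rng, n, chroms=("chr1",), size=10_000):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, size - 50))
        end = start + int(rng.integers(1, 50))
        out.append(GenomicInterval(chrom, start, end))
    return out
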