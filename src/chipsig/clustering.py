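"""k-means clustering of signal matrices and randomized-SSE choice of k.

The number of clusters is chosen by clustering the real matrix and a set
of randomized instances (each column independently permuted, which keeps
per-library marginals but destroys the joint structure) for every k in a
range, and taking the k at which the randomized-minus-actual SSE gap is
largest.  Densities are log-transformed and column-standardized before
clustering so no single high-dynamic-range library dominates the Euclidean
metric; cluster profiles are always reported on the raw density scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .intervals import ELEMENT_CLASSES, GeneIndex, GeneModel, Peak
from .intervals import element_distribution
from .signal import SignalMatrix


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray  # 1-based cluster index per locus
    centroids: np.ndarray  # k x n_libraries, in preprocessed space
    sse: float  # within-cluster sum of squared distances

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in [1..k]")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    def to_frame(self, locus_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"locus_id": locus_ids, "cluster": self.labels}
        )


def preprocess(
    values: np.ndarray,
    log_transform: bool = True,
    z_score: bool = True,
) -> np.ndarray:
    """log2(1 + density) then per-column standardization (both toggleable)."""
    x = np.asarray(values, dtype=float)
    if log_transform:
        x = np.log2(1.0 + x)
    if z_score:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - mu) / sd
    return x


def kmeans_cluster(
    matrix: SignalMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    log_transform: bool = True,
    z_score: bool = True,
) -> ClusteringResult:
    """Best-of-``n_init`` k-means on the preprocessed signal matrix.

    Uses k-means++ seeding and squared-Euclidean distance; deterministic
    under a fixed seed.  The reported SSE is the within-cluster sum of
    squared distances in the preprocessed space.
    """
    n = matrix.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= {n} loci, got k={k}")
    x = preprocess(matrix.values, log_transform, z_score)
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        init="k-means++",
        max_iter=300,
        tol=1e-4,
        random_state=int(seed) % (2**32 - 1),
    ).fit(x)
    return ClusteringResult(
        k=k,
        labels=km.labels_ + 1,
        centroids=km.cluster_centers_,
        sse=float(km.inertia_),
    )


def randomize_matrix(matrix: SignalMatrix, seed: int = 0) -> SignalMatrix:
    """Independently permute each column across rows.

    Preserves every library's marginal density distribution while
    destroying locus-level co-occupancy structure.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for j in range(values.shape[1]):
        rng.shuffle(values[:, j])
    return SignalMatrix(
        locus_ids=list(matrix.locus_ids),
        library_names=list(matrix.library_names),
        values=values,
    )


@dataclass
class KSelectionCurve:
    """Actual-vs-randomized SSE over a range of k, and the chosen k."""

    k_values: np.ndarray
    sse_actual: np.ndarray
    sse_random_mean: np.ndarray
    sse_random_sd: np.ndarray
    chosen_k: int

    @property
    def gap(self) -> np.ndarray:
        return self.sse_random_mean - self.sse_actual

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "sse_actual": self.sse_actual,
                "sse_random_mean": self.sse_random_mean,
                "sse_random_sd": self.sse_random_sd,
                "gap": self.gap,
            }
        )


def select_k(
    matrix: SignalMatrix,
    k_max: int = 15,
    n_random: int = 250,
    seed: int = 0,
    n_init: int = 10,
    log_transform: bool = True,
    z_score: bool = True,
) -> KSelectionCurve:
    """Choose k by maximizing the randomized-minus-actual SSE gap.

    For each ``k`` in ``1..k_max`` the data and a shared set of
    ``n_random`` randomized instances are clustered identically; the chosen
    k maximizes ``mean(randomized SSE) - actual SSE``, ties broken toward
    smaller k.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if k_max > matrix.shape[0]:
        raise ValueError("k_max exceeds the number of loci")
    rng = np.random.default_rng(seed)
    randomized = [
        randomize_matrix(matrix, int(rng.integers(2**31)))
        for _ in range(n_random)
    ]
    ks = np.arange(1, k_max + 1)
    sse_actual = np.zeros(k_max)
    sse_rand = np.zeros((k_max, n_random))
    for i, k in enumerate(ks):
        k_seed = int(rng.integers(2**31))
        sse_actual[i] = kmeans_cluster(
            matrix, int(k), seed=k_seed, n_init=n_init,
            log_transform=log_transform, z_score=z_score,
        ).sse
        for r, rmat in enumerate(randomized):
            sse_rand[i, r] = kmeans_cluster(
                rmat, int(k), seed=k_seed, n_init=n_init,
                log_transform=log_transform, z_score=z_score,
            ).sse
    gap = sse_rand.mean(axis=1) - sse_actual
    chosen = int(ks[int(np.argmax(gap))])  # argmax returns first max: small-k tie-break
    return KSelectionCurve(
        k_values=ks,
        sse_actual=sse_actual,
        sse_random_mean=sse_rand.mean(axis=1),
        sse_random_sd=sse_rand.std(axis=1),
        chosen_k=chosen,
    )


def cluster_profiles(
    matrix: SignalMatrix, labels: np.ndarray
) -> pd.DataFrame:
    """Per-cluster mean raw density per library (cluster x library table)."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != matrix.shape[0]:
        raise ValueError("labels length must equal the number of loci")
    rows = {}
    for c in sorted(set(labels.tolist())):
        mask = labels == c
        if not mask.any():
            warnings.warn(f"cluster {c} is empty; profile undefined",
                          stacklevel=2)
            rows[c] = np.full(matrix.shape[1], np.nan)
        else:
            rows[c] = matrix.values[mask].mean(axis=0)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=matrix.library_names
    )
    df.index.name = "cluster"
    return df


def semantic_relabel(
    matrix: SignalMatrix,
    result: ClusteringResult,
    repressor_lib: str = "N-CoR",
    active_lib: str = "H3K4me3",
) -> ClusteringResult:
    """Rename clusters so labels carry co-occupancy semantics.

    Cluster 1 becomes the cluster with the highest mean co-repressor
    (default N-CoR) signal, cluster 2 the highest mean active-promoter mark
    (default H3K4me3) among the rest, remaining clusters keep their raw-mean
    repressor ordering.  This makes downstream cluster-1 dominance rules
    deterministic and interpretable.
    """
    profiles = cluster_profiles(matrix, result.labels)
    order: list[int] = []
    remaining = list(profiles.index)
    c1 = int(profiles[repressor_lib].idxmax())
    order.append(c1)
    remaining.remove(c1)
    if remaining:
        c2 = int(profiles.loc[remaining, active_lib].idxmax())
        order.append(c2)
        remaining.remove(c2)
    order.extend(
        int(c) for c in
        profiles.loc[remaining, repressor_lib]
        .sort_values(ascending=False).index
    )
    mapping = {old: new + 1 for new, old in enumerate(order)}
    new_labels = np.array([mapping[int(l)] for l in result.labels])
    return ClusteringResult(
        k=result.k,
        labels=new_labels,
        centroids=result.centroids[[c - 1 for c in order]],
        sse=result.sse,
    )


def element_distribution_by_cluster(
    loci: list[Peak],
    labels: np.ndarray,
    genes: list[GeneModel] | GeneIndex,
    promoter_flank: int = 2000,
    tts_flank: int = 2000,
    backgrounds: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Five-class element fractions per cluster, plus expected baselines.

    ``backgrounds`` maps a baseline name (e.g. ``"random"`` or
    ``"motif_matched"``) to a list of sampled loci; each contributes an
    expected-fraction row.  Every row sums to 1.
    """
    labels = np.asarray(labels, dtype=int)
    index = (
        genes
        if isinstance(genes, GeneIndex)
        else GeneIndex(genes, promoter_flank, tts_flank)
    )
    rows: dict[str, dict[str, float]] = {}
    for c in sorted(set(labels.tolist())):
        cluster_loci = [
            p.interval for p, l in zip(loci, labels) if l == c
        ]
        rows[f"cluster_{c}"] = element_distribution(cluster_loci, index)
    for name, bg_loci in (backgrounds or {}).items():
        rows[f"expected_{name}"] = element_distribution(list(bg_loci), index)
    df = pd.DataFrame.from_dict(rows, orient="index")[list(ELEMENT_CLASSES)]
    df.index.name = "set"
    return df
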