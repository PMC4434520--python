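"""Linking occupancy clusters to differential gene expression.

Probe-level log2 expression is reduced to one probe per gene (largest
interquartile range), fitted gene-wise with a blocked linear model
(``~0 + block + condition``), and summarized by empirical-Bayes moderated
t statistics.  Loci are assigned to genes by nearest TSS; a gene touched by
loci from several clusters is assigned under a dominance rule in which
cluster 1 (the repressor-co-occupied signature) always wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .intervals import GeneModel, Peak


# ---------------------------------------------------------------------------
# Probe handling
# ---------------------------------------------------------------------------


def dedup_probes_by_iqr(
    probes: pd.DataFrame, sample_cols: list[str] | None = None
) -> pd.DataFrame:
    """Keep one probe per gene: the one with the largest IQR of its values.

    ``probes`` must have a ``probe_id`` index (or column) and a ``gene_id``
    column; remaining columns (or ``sample_cols``) are per-sample log2
    values.  IQR ties are broken toward the lexicographically smallest
    probe id.  Returns a gene-indexed table with a ``probe_id`` column.
    """
    df = probes.reset_index() if probes.index.name == "probe_id" else probes.copy()
    if "probe_id" not in df.columns or "gene_id" not in df.columns:
        raise ValueError("need probe_id and gene_id columns")
    if sample_cols is None:
        sample_cols = [c for c in df.columns if c not in ("probe_id", "gene_id")]
    vals = df[sample_cols].to_numpy(dtype=float)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)
    df = df.assign(_iqr=q75 - q25)
    df = df.sort_values(
        ["gene_id", "_iqr", "probe_id"], ascending=[True, False, True]
    )
    best = df.groupby("gene_id", sort=True).head(1).drop(columns="_iqr")
    return best.set_index("gene_id")[["probe_id", *sample_cols]]


# ---------------------------------------------------------------------------
# Blocked linear model and moderated t
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Per-sample condition and blocking factors for the expression model.

    ``condition`` holds two levels (knockdown vs control); ``block`` is the
    batch/time-point factor.  The fitted contrast is
    ``treatment_level - reference``, matching a model of the form
    ``~0 + block + condition``.
    """

    samples: list[str]
    condition: list[str]
    block: list[str]
    treatment_level: str | None = None

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.condition) == len(self.block)):
            raise ValueError("samples/condition/block lengths differ")
        levels = sorted(set(self.condition))
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 condition levels, got {levels}")
        if self.treatment_level is None:
            self.treatment_level = levels[-1]
        if self.treatment_level not in levels:
            raise ValueError("treatment_level not found among conditions")
        for b in set(self.block):
            conds = {
                c for c, bb in zip(self.condition, self.block) if bb == b
            }
            if len(conds) < 2:
                raise ValueError(
                    f"block {b!r} lacks both conditions; contrast not estimable"
                )

    @property
    def blocks(self) -> list[str]:
        return sorted(set(self.block))

    def design_matrix(self) -> np.ndarray:
        """Columns: one indicator per block, then the treatment indicator."""
        blocks = self.blocks
        n = len(self.samples)
        x = np.zeros((n, len(blocks) + 1))
        for i, (b, c) in enumerate(zip(self.block, self.condition)):
            x[i, blocks.index(b)] = 1.0
            if c == self.treatment_level:
                x[i, -1] = 1.0
        return x

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "condition": self.condition,
             "block": self.block}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "DesignSpec":
        return cls(
            samples=list(df["sample"].astype(str)),
            condition=list(df["condition"].astype(str)),
            block=list(df["block"].astype(str)),
            **kw,
        )


@dataclass
class FitResult:
    """Per-gene least-squares fits from the blocked linear model."""

    table: pd.DataFrame  # index gene_id; columns log2fc, s2, df
    stdunscaled: float  # sqrt of the contrast's unscaled variance factor
    df_residual: int


def fit_blocked_de(expr: pd.DataFrame, design: DesignSpec) -> FitResult:
    """Gene-wise OLS of log2 expression on block + condition.

    ``expr`` is gene-indexed with one column per sample (extra annotation
    columns such as ``probe_id`` are ignored).  The condition coefficient
    is the log2 fold-change (treatment minus reference) adjusted for block
    effects; its unscaled standard deviation and the residual variance/df
    are returned for moderated-t computation.
    """
    y = expr[design.samples].to_numpy(dtype=float)
    x = design.design_matrix()
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError("singular design matrix")
    df_resid = n - rank
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x p
    resid = y - beta @ x.T
    rss = (resid**2).sum(axis=1)
    s2 = rss / df_resid
    # exact fits leave only float rounding in the residuals
    zero = s2 <= 1e-18 * max(float(np.mean(y**2)), 1.0)
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} genes have zero residual variance",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {"log2fc": beta[:, -1], "s2": s2, "df": df_resid},
        index=expr.index,
    )
    return FitResult(
        table=table,
        stdunscaled=float(np.sqrt(xtx_inv[-1, -1])),
        df_residual=df_resid,
    )


def _trigamma_inverse(x: float) -> float:
    """Invert the trigamma function by Newton iteration (limma-style)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) for residual variances.

    Matches the mean and variance of ``log(s2)`` against the theoretical
    scaled-F log-moments (digamma/trigamma), as in empirical-Bayes variance
    moderation.  ``d0 = inf`` signals no excess spread (full shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need >= 10 positive residual variances")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    excess = z.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(
            np.exp(
                e.mean()
                + float(special.digamma(d0 / 2.0))
                - np.log(d0 / 2.0)
            )
        )
    return float(d0), s0_2


def moderated_t(
    fit: FitResult, prior: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Empirical-Bayes moderated t tests on the blocked-model fits.

    The posterior variance shrinks each gene's residual variance toward the
    prior value: ``(d0*s0^2 + df*s^2) / (d0 + df)``; t uses ``d0 + df``
    degrees of freedom.  ``prior=(0, .)`` gives ordinary t statistics;
    ``prior=(inf, s0^2)`` uses the common variance for every gene.

    Returns a gene-indexed frame with log2fc, t, p (two-sided), df, s2_post
    and attrs ``d0``/``s0_2``.
    """
    tab = fit.table
    df = float(fit.df_residual)
    if prior is None:
        d0, s0_2 = estimate_variance_prior(tab["s2"].to_numpy(), df)
    else:
        d0, s0_2 = float(prior[0]), float(prior[1])
    s2 = tab["s2"].to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post) * fit.stdunscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = tab["log2fc"].to_numpy() / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "log2fc": tab["log2fc"],
            "t": t,
            "p": p,
            "df": df_total if np.isfinite(df_total) else np.inf,
            "s2_post": s2_post,
        },
        index=tab.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


# ---------------------------------------------------------------------------
# Locus -> gene assignment and the cluster dominance rule
# ---------------------------------------------------------------------------


def assign_locus_to_gene(
    loci: list[Peak],
    genes: list[GeneModel],
    max_distance: int | None = None,
) -> dict[str, str]:
    """Assign each locus the gene with the TSS nearest to its summit.

    Distance ties are broken toward the smaller gene id.  Loci on
    chromosomes without genes (or beyond ``max_distance``) are left out and
    reported with a warning.
    """
    if not genes:
        raise ValueError("gene table is empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arrays[chrom] = (
            np.array([t for t, _ in pairs]),
            [gid for _, gid in pairs],
        )
    out: dict[str, str] = {}
    unassigned = 0
    for peak in loci:
        if peak.chrom not in arrays:
            unassigned += 1
            continue
        tss, gids = arrays[peak.chrom]
        i = int(np.searchsorted(tss, peak.summit))
        cands = []
        for j in (i - 1, i):
            if 0 <= j < tss.size:
                cands.append((abs(int(tss[j]) - peak.summit), gids[j]))
        # distance ties (incl. identical TSSs) -> smallest gene id
        lo = i
        while lo - 2 >= 0 and tss[lo - 2] == tss[i - 1]:
            cands.append((abs(int(tss[lo - 2]) - peak.summit), gids[lo - 2]))
            lo -= 1
        hi = i
        while hi + 1 < tss.size and tss[hi + 1] == tss[i]:
            cands.append((abs(int(tss[hi + 1]) - peak.summit), gids[hi + 1]))
            hi += 1
        dist, gid = min(cands)
        if max_distance is not None and dist > max_distance:
            unassigned += 1
            continue
        out[peak.name] = gid
    if unassigned:
        warnings.warn(
            f"{unassigned} loci unassigned (no gene on chromosome or beyond "
            "max_distance)",
            stacklevel=2,
        )
    return out


@dataclass
class GeneClusterAssignment:
    gene_id: str
    cluster: int
    supporting_loci: list[str] = field(default_factory=list)


def assign_gene_cluster(
    locus_gene: dict[str, str], locus_cluster: dict[str, int]
) -> list[GeneClusterAssignment]:
    """Exclusive gene cluster under the cluster-1 dominance rule.

    A gene is assigned the minimum cluster label among its loci (dominance
    order 1 > 2 > 3): any cluster-1 locus makes the gene a cluster-1 gene,
    otherwise cluster 2 beats cluster 3.
    """
    per_gene: dict[str, list[str]] = {}
    for locus, gene in locus_gene.items():
        if locus not in locus_cluster:
            raise KeyError(f"locus {locus!r} has no cluster")
        per_gene.setdefault(gene, []).append(locus)
    out = []
    for gene in sorted(per_gene):
        loci = sorted(per_gene[gene])
        cluster = min(locus_cluster[l] for l in loci)
        out.append(GeneClusterAssignment(gene, int(cluster), loci))
    return out


def assignment_frame(
    assignments: list[GeneClusterAssignment],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.gene_id, a.cluster, ",".join(a.supporting_loci))
            for a in assignments
        ],
        columns=["gene_id", "cluster", "supporting_loci"],
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Distribution comparisons and association tests
# ---------------------------------------------------------------------------


def t_scores_by_cluster(
    de: pd.DataFrame, assignments: list[GeneClusterAssignment]
) -> dict[int, np.ndarray]:
    """t scores of assigned genes, grouped by exclusive cluster."""
    out: dict[int, list[float]] = {}
    for a in assignments:
        if a.gene_id in de.index:
            out.setdefault(a.cluster, []).append(float(de.loc[a.gene_id, "t"]))
    return {c: np.array(v) for c, v in sorted(out.items())}


def t_cdf_by_cluster(
    de: pd.DataFrame, assignments: list[GeneClusterAssignment]
) -> pd.DataFrame:
    """Empirical C(t) and a kernel density P(t) per cluster (long format)."""
    groups = t_scores_by_cluster(de, assignments)
    rows = []
    for cluster, t in groups.items():
        if t.size == 0:
            warnings.warn(f"cluster {cluster} has no genes", stacklevel=2)
            continue
        t = np.sort(t)
        cdf = np.arange(1, t.size + 1) / t.size
        if t.size > 1 and t.std() > 0:
            dens = stats.gaussian_kde(t)(t)
        else:
            dens = np.full(t.size, np.nan)
        for ti, ci, di in zip(t, cdf, dens):
            rows.append((cluster, ti, ci, di))
    return pd.DataFrame(rows, columns=["cluster", "t", "cdf", "density"])


def compare_cluster_shift(
    t_a, t_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Welch two-sample t-test comparing two clusters' t-score distributions.

    ``alternative='greater'`` tests for ``t_a`` shifted to higher values.
    """
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    if t_a.size < 2 or t_b.size < 2:
        raise ValueError("each group needs >= 2 values")
    res = stats.ttest_ind(t_a, t_b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def substantially_altered(
    de: pd.DataFrame,
    fc_cut: float = 1.0,
    p_cut: float = 0.01,
    abs_fc: bool = False,
) -> pd.Series:
    """Flag genes with large, significant expression change.

    Default (signed): ``log2fc > fc_cut and p < p_cut`` — up-regulation on
    knockdown, i.e. genes the factor represses.  ``abs_fc=True`` accepts
    change in either direction (``|log2fc| > fc_cut``).
    """
    fc = de["log2fc"]
    mag = fc.abs() if abs_fc else fc
    return (mag > fc_cut) & (de["p"] < p_cut)


def fisher_cluster_association(
    assignments: list[GeneClusterAssignment],
    altered: pd.Series,
    cluster_ref: int,
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact association between cluster-1 membership and alteration.

    Builds the 2x2 table with rows {cluster 1, ``cluster_ref``} and columns
    {altered, not altered}; the two-sided p sums hypergeometric
    probabilities no larger than the observed table's.  Returns
    ``(odds_ratio, p, table)``.
    """
    table = np.zeros((2, 2), dtype=int)
    for a in assignments:
        if a.cluster == 1:
            row = 0
        elif a.cluster == cluster_ref:
            row = 1
        else:
            continue
        if a.gene_id not in altered.index:
            continue
        col = 0 if bool(altered.loc[a.gene_id]) else 1
        table[row, col] += 1
    if table.sum(axis=1).min() == 0:
        raise ValueError("one of the compared clusters has no scored genes")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table
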