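"""Position weight matrices, discriminative motif discovery, and motif scanning.

The discovery routine searches for a PWM that best separates a positive
sequence set from a negative one, using the area under the ROC curve (AUC)
of per-sequence best-site scores as the objective and simulated annealing
with Metropolis-Hastings column moves as the optimizer.  Site p-values are
exact under an i.i.d. background, computed by dynamic programming over
discretized log-odds scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = "ACGT"
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

#: index of the "unknown base" row appended to score matrices; scores 0.
N_INDEX = 4


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T with a background model.

    Parameters
    ----------
    probs
        ``(width, 4)`` array; every row sums to 1.
    background
        Length-4 base frequencies summing to 1; default uniform.
    pseudocount
        Additive regularizer applied when forming log-odds scores, so that
        zero probabilities never produce ``-inf``.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a (width, 4) matrix")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM row must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_consensus(
        cls, consensus: str, match_prob: float = 0.85, **kw
    ) -> "PWM":
        """Sharp PWM putting ``match_prob`` on each consensus base."""
        off = (1.0 - match_prob) / 3.0
        probs = np.full((len(consensus), 4), off)
        for i, base in enumerate(consensus.upper()):
            probs[i, ALPHABET.index(base)] = match_prob
        return cls(probs, **kw)

    @classmethod
    def from_counts(cls, counts: np.ndarray, alpha: float = 0.5, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float) + alpha
        return cls(counts / counts.sum(axis=1, keepdims=True), **kw)

    def sample_site(self, rng: np.random.Generator) -> str:
        idx = [rng.choice(4, p=row) for row in self.probs]
        return "".join(ALPHABET[i] for i in idx)

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background.copy(),
                   self.pseudocount)

    def to_meme(self, path, name: str = "motif_1") -> None:
        """Write the PWM as a minimal MEME motif file."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write("Background letter frequencies\n")
            fh.write("A %.5f C %.5f G %.5f T %.5f\n\n" % tuple(self.background))
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {self.width}\n"
            )
            for row in self.probs:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))

    @classmethod
    def from_meme(cls, path) -> "PWM":
        background = np.full(4, 0.25)
        rows: list[list[float]] = []
        in_matrix = False
        with open(path) as fh:
            lines = iter(fh)
            for line in lines:
                if line.startswith("Background letter frequencies"):
                    parts = next(lines).split()
                    background = np.array(
                        [float(parts[i]) for i in (1, 3, 5, 7)]
                    )
                elif line.startswith("letter-probability matrix"):
                    in_matrix = True
                elif in_matrix:
                    parts = line.split()
                    if len(parts) != 4:
                        break
                    rows.append([float(x) for x in parts])
        if not rows:
            raise ValueError(f"no letter-probability matrix found in {path}")
        return cls(np.array(rows), background)


def log_odds(pwm: PWM) -> np.ndarray:
    """Per-position log2 odds of the PWM versus its background.

    Probabilities are regularized as ``(p + c) / (1 + 4c)`` with the PWM's
    pseudocount ``c`` before taking the ratio, so entries are always finite.
    """
    if np.any(pwm.background <= 0):
        raise ValueError("background frequencies must be positive")
    adj = (pwm.probs + pwm.pseudocount) / (1.0 + 4.0 * pwm.pseudocount)
    return np.log2(adj / pwm.background)


def _lod5(lod: np.ndarray) -> np.ndarray:
    """Score matrix with a fifth zero column for non-ACGT bases."""
    return np.hstack([lod, np.zeros((lod.shape[0], 1))])


def _window_index_matrix(idx: np.ndarray, width: int) -> np.ndarray:
    """All length-``width`` windows of an encoded sequence, one per row."""
    return np.lib.stride_tricks.sliding_window_view(idx, width)


def window_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds of every window on the forward and reverse strands.

    Returns ``(fwd, rev)`` where ``rev[i]`` scores the reverse-complement
    site whose leftmost forward-strand base is at offset ``i``.
    """
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence length {len(seq)} < motif width {w}")
    lod = _lod5(log_odds(pwm))
    idx = encode_sequence(seq)
    wins = _window_index_matrix(idx, w)
    pos = np.arange(w)
    fwd = lod[pos, wins].sum(axis=1)
    # Scanning the reverse strand == scanning forward with the RC score matrix.
    rc_lod = np.vstack([lod[::-1, [3, 2, 1, 0]].T, lod[::-1, 4]]).T
    rev = rc_lod[pos, wins].sum(axis=1)
    return fwd, rev


def best_site_score(pwm: PWM, seq: str) -> float:
    """Maximum log-odds over all windows on both strands."""
    fwd, rev = window_scores(pwm, seq)
    return float(max(fwd.max(), rev.max()))


def best_site_scores(pwm: PWM, seqs: list[str]) -> np.ndarray:
    return np.array([best_site_score(pwm, s) for s in seqs])


def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos = neg).

    Equals the area under the ROC curve of the score as a classifier of
    positive versus negative sequences.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# Simulated annealing over PWMs
# ---------------------------------------------------------------------------

_ALPHA_FLOOR = 1e-3  # keeps Dirichlet proposal parameters strictly positive


def propose_move(
    pwm: PWM, rng: np.random.Generator,
    step_scale: float | tuple[float, float] = 50.0,
) -> tuple[PWM, int]:
    """Perturb one uniformly chosen column of the PWM.

    The new column is drawn from a Dirichlet centered on the current column
    with total concentration ``step_scale``; large ``step_scale`` means small
    steps.  A ``(lo, hi)`` tuple draws the concentration log-uniformly per
    move, mixing coarse escape moves with fine refinements.  Returns the
    proposed PWM, the perturbed column index, and the concentration used.
    """
    if isinstance(step_scale, tuple):
        lo, hi = step_scale
        step_scale = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    j = int(rng.integers(pwm.width))
    probs = pwm.probs.copy()
    alpha = probs[j] * step_scale + _ALPHA_FLOOR
    new_col = rng.dirichlet(alpha)
    # guard exact zeros from numerical underflow
    new_col = np.maximum(new_col, 1e-9)
    probs[j] = new_col / new_col.sum()
    return PWM(probs, pwm.background.copy(), pwm.pseudocount), j, step_scale


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum()
        + ((alpha - 1.0) * np.log(x)).sum()
    )


@dataclass
class AnnealResult:
    """Outcome of a discriminative-motif annealing run."""

    pwm: PWM
    best_auc: float
    trace: pd.DataFrame  # columns: step, temperature, current_auc, best_auc


class _ScoreCache:
    """Incremental best-site scores for a fixed sequence set.

    Window base indices for both strands are precomputed; when a single PWM
    column changes, every window score is updated with one gather and one
    add, and per-sequence maxima are recomputed by segmented reduction.
    All sequences must be at least as long as the motif.
    """

    def __init__(self, seqs: list[str], width: int):
        self.width = width
        wins = []
        starts = []
        total = 0
        for s in seqs:
            idx = encode_sequence(s)
            if idx.size < width:
                raise ValueError("sequence shorter than motif width")
            fw = _window_index_matrix(idx, width)
            # reverse-complement windows, expressed in forward coordinates
            rc = encode_sequence(reverse_complement(s))
            rv = _window_index_matrix(rc, width)
            both = np.vstack([fw, rv])
            wins.append(both)
            starts.append(total)
            total += both.shape[0]
        self.windows = np.vstack(wins).astype(np.int8)
        self.starts = np.array(starts)
        self.cols = [
            np.ascontiguousarray(self.windows[:, j]) for j in range(width)
        ]
        self.scores = np.zeros(total)

    def set_matrix(self, lod5: np.ndarray) -> None:
        pos = np.arange(self.width)
        self.scores = lod5[pos, self.windows].sum(axis=1)

    def delta_for(self, j: int, old_col5: np.ndarray,
                  new_col5: np.ndarray) -> np.ndarray:
        return (new_col5 - old_col5)[self.cols[j]]

    def best_per_sequence(self, scores: np.ndarray | None = None) -> np.ndarray:
        s = self.scores if scores is None else scores
        return np.maximum.reduceat(s, self.starts)


def estimate_background(seqs: list[str]) -> np.ndarray:
    """Base frequencies over a sequence collection (ignoring non-ACGT)."""
    counts = np.zeros(4)
    for s in seqs:
        idx = encode_sequence(s)
        counts += np.bincount(idx[idx < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def random_pwm(width: int, rng: np.random.Generator,
               background: np.ndarray | None = None) -> PWM:
    """PWM with columns drawn from a flat Dirichlet."""
    probs = rng.dirichlet(np.ones(4), size=width)
    bg = np.full(4, 0.25) if background is None else background
    return PWM(probs, bg)


def anneal_discriminative_motif(
    pos_seqs: list[str],
    neg_seqs: list[str],
    width: int = 10,
    schedule: tuple[float, float, int] = (0.01, 0.999, 20_000),
    seed: int = 0,
    step_scale: float | tuple[float, float] = (5.0, 200.0),
    shift_prob: float = 0.1,
    n_cycles: int = 3,
    reheat_decay: float = 1.0,
    background: np.ndarray | None = None,
    exact_mh: bool = False,
    trace_every: int = 1,
    init: PWM | None = None,
) -> AnnealResult:
    """Search for the PWM that best separates two sequence sets.

    Starting from a random PWM, Metropolis-Hastings moves are accepted with
    probability ``min(1, exp((AUC' - AUC) / T))`` under a geometric
    temperature schedule ``T0 * cooling**step``.  The objective is the AUC
    of per-sequence best-site log-odds scores, positives versus negatives.
    Most moves resample one column (:func:`propose_move`); with probability
    ``shift_prob`` the whole matrix is instead shifted by one position
    (a fresh flat-Dirichlet column enters at the vacated end), which lets
    the search escape off-register local optima that column moves alone
    cannot fix.  The cooling schedule is cyclic: the step budget is split
    into ``n_cycles`` anneals; cycle ``c`` reheats to ``T0 *
    reheat_decay**c``, so a run trapped early in a poor basin gets fresh
    chances to escape while later cycles concentrate on fine polish.  The
    best PWM ever visited is returned.

    Parameters
    ----------
    schedule
        ``(T0, cooling_factor, n_steps)`` with ``T0 > 0`` and cooling factor
        in ``(0, 1]``.
    exact_mh
        When true, the asymmetric-proposal Hastings correction for the
        Dirichlet column move is included in the acceptance ratio; by
        default the proposal is treated as symmetric.
    """
    t0, cooling, n_steps = schedule
    if t0 <= 0:
        raise ValueError("initial temperature must be positive")
    if not (0 < cooling <= 1):
        raise ValueError("cooling factor must lie in (0, 1]")
    if not pos_seqs or not neg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    rng = np.random.default_rng(seed)
    if background is None:
        background = estimate_background(list(pos_seqs) + list(neg_seqs))

    n_pos = len(pos_seqs)
    cache = _ScoreCache(list(pos_seqs) + list(neg_seqs), width)
    if init is None:
        current = random_pwm(width, rng, background)
    else:
        if init.width != width:
            raise ValueError("init PWM width mismatch")
        current = PWM(init.probs.copy(), np.asarray(background, dtype=float))
    lod5 = _lod5(log_odds(current))
    cache.set_matrix(lod5)

    def objective() -> float:
        best = cache.best_per_sequence()
        return auc(best[:n_pos], best[n_pos:])

    current_auc = objective()
    best_pwm, best_auc = current, current_auc
    temp = t0
    rec_step, rec_t, rec_cur, rec_best = [0], [temp], [current_auc], [best_auc]
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    cycle_len = max(n_steps // n_cycles, 1) if n_steps else 1

    for step in range(1, n_steps + 1):
        if step % cycle_len == 0 and step < n_steps:
            temp = t0 * reheat_decay ** (step // cycle_len)  # reheat
        is_shift = rng.random() < shift_prob
        if is_shift:
            probs = current.probs.copy()
            fresh = rng.dirichlet(np.ones(4))
            if rng.random() < 0.5:
                probs = np.vstack([probs[1:], fresh])  # shift left
            else:
                probs = np.vstack([fresh, probs[:-1]])  # shift right
            proposal = PWM(probs, current.background.copy(),
                           current.pseudocount)
            prop_lod5 = _lod5(log_odds(proposal))
            new_scores = None
            saved = cache.scores
            cache.set_matrix(prop_lod5)
            best = cache.best_per_sequence()
            cache.scores, new_scores = saved, cache.scores
        else:
            proposal, j, used_scale = propose_move(current, rng, step_scale)
            new_lod5_col = _lod5(log_odds(proposal))[j]
            delta = cache.delta_for(j, lod5[j], new_lod5_col)
            new_scores = cache.scores + delta
            best = cache.best_per_sequence(new_scores)
        new_auc = auc(best[:n_pos], best[n_pos:])

        log_accept = (new_auc - current_auc) / temp
        if exact_mh and not is_shift:
            a_fwd = current.probs[j] * used_scale + _ALPHA_FLOOR
            a_rev = proposal.probs[j] * used_scale + _ALPHA_FLOOR
            log_accept += _dirichlet_logpdf(current.probs[j], a_rev)
            log_accept -= _dirichlet_logpdf(proposal.probs[j], a_fwd)
        if log_accept >= 0 or rng.random() < math.exp(max(log_accept, -700)):
            current = proposal
            current_auc = new_auc
            if is_shift:
                lod5 = _lod5(log_odds(current))
            else:
                lod5[j] = new_lod5_col
            cache.scores = new_scores
            if new_auc > best_auc:
                best_pwm, best_auc = proposal, new_auc
        temp *= cooling
        if step % trace_every == 0 or step == n_steps:
            rec_step.append(step)
            rec_t.append(temp)
            rec_cur.append(current_auc)
            rec_best.append(best_auc)

    trace = pd.DataFrame(
        {
            "step": rec_step,
            "temperature": rec_t,
            "current_auc": rec_cur,
            "best_auc": rec_best,
        }
    )
    return AnnealResult(pwm=best_pwm, best_auc=float(best_auc), trace=trace)


def pwm_alignment_correlation(
    found: PWM, reference: PWM, min_overlap: int | None = None
) -> float:
    """Mean per-column Pearson correlation after best offset/strand alignment.

    The two matrices are slid against each other (both orientations of
    ``found``), allowing partial overlaps of at least ``min_overlap``
    columns (default: half the narrower width, at least 4); the alignment
    maximizing the mean column-wise correlation of the overlapping
    probability columns is reported.  Used to quantify how well a
    discovered motif recovers a known (e.g. planted) one.
    """
    if min_overlap is None:
        min_overlap = max(4, min(found.width, reference.width) // 2)

    def mean_col_corr(a: np.ndarray, b: np.ndarray) -> float:
        cors = []
        for x, y in zip(a, b):
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(x, y)[0, 1]))
        return float(np.mean(cors))

    best = -1.0
    wb = reference.width
    for cand in (found, found.reverse_complement()):
        a = cand.probs
        wa = a.shape[0]
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(off, 0), min(wa, off + wb)
            if hi_a - lo_a < min_overlap:
                continue
            lo_b, hi_b = lo_a - off, hi_a - off
            best = max(
                best, mean_col_corr(a[lo_a:hi_a], reference.probs[lo_b:hi_b])
            )
    return best


# ---------------------------------------------------------------------------
# Exact scan p-values by dynamic programming
# ---------------------------------------------------------------------------


@dataclass
class ScoreDistribution:
    """Null distribution of a PWM site score under the i.i.d. background.

    Scores are discretized to integer multiples of ``granularity`` (bits).
    ``tail[i]`` is ``P(score >= (i + min_score_bin) * granularity)`` for a
    single site on one strand.
    """

    granularity: float
    min_score_bin: int
    tail: np.ndarray
    qlod: np.ndarray  # (width, 4) integer per-position scores

    def pvalue_from_bins(self, score_bins) -> np.ndarray:
        """Tail probability for integer (binned) total scores."""
        i = np.asarray(score_bins) - self.min_score_bin
        i = np.clip(i, 0, self.tail.size - 1)
        return self.tail[i]

    def pvalue(self, score: float) -> float:
        """Tail probability P(site score >= ``score``) under the background."""
        b = int(round(score / self.granularity))
        if b <= self.min_score_bin:
            return 1.0
        if b > self.min_score_bin + self.tail.size - 1:
            return 0.0
        return float(self.pvalue_from_bins([b])[0])


def score_pvalue_table(
    pwm: PWM, granularity: float = 0.01,
    background: np.ndarray | None = None,
) -> ScoreDistribution:
    """Exact null distribution of site scores by positional convolution.

    Log-odds scores are rounded to ``granularity``-bit bins; the DP then
    convolves the per-position score distributions under the background base
    frequencies, which is exact for the discretized score.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bg = pwm.background if background is None else np.asarray(background)
    lod = log_odds(pwm)
    qlod = np.round(lod / granularity).astype(np.int64)
    lo = int(qlod.min(axis=1).sum())
    hi = int(qlod.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    # running support [cur_lo, cur_lo + len) in bin units
    cur_lo = 0
    cur = np.array([1.0])
    for i in range(pwm.width):
        row = qlod[i]
        new_lo = cur_lo + int(row.min())
        new_hi = cur_lo + cur.size - 1 + int(row.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(row[b]) - new_lo
            new[off:off + cur.size] += cur * bg[b]
        cur, cur_lo = new, new_lo
    dist[cur_lo - lo: cur_lo - lo + cur.size] = cur
    tail = np.minimum(np.cumsum(dist[::-1])[::-1], 1.0)
    return ScoreDistribution(granularity=granularity, min_score_bin=lo,
                             tail=tail, qlod=qlod)


@dataclass(frozen=True)
class ScanHit:
    """A single motif match in a scanned sequence."""

    locus_id: str
    offset: int  # 0-based, leftmost forward-strand base of the site
    strand: str  # '+' or '-'
    score: float  # log2 odds (bits)
    p_value: float


def scan_sequences(
    pwm: PWM,
    seqs: list[tuple[str, str]],
    p_threshold: float = 1e-4,
    granularity: float = 0.01,
    background: np.ndarray | None = None,
    table: ScoreDistribution | None = None,
) -> list[ScanHit]:
    """Report every site on either strand with p-value below the threshold.

    ``seqs`` is a list of ``(locus_id, sequence)`` pairs.  P-values come from
    :func:`score_pvalue_table`; the reported score is the exact (undiscretized)
    log-odds of the site.
    """
    if table is None:
        table = score_pvalue_table(pwm, granularity, background)
    w = pwm.width
    lod5 = _lod5(log_odds(pwm))
    qlod5 = np.hstack([table.qlod, np.zeros((w, 1), dtype=np.int64)])
    rc_cols = [3, 2, 1, 0, 4]
    pos = np.arange(w)
    hits: list[ScanHit] = []
    for locus_id, seq in seqs:
        if len(seq) < w:
            continue
        idx = encode_sequence(seq)
        wins = _window_index_matrix(idx, w)
        for strand in "+-":
            if strand == "+":
                sc = lod5[pos, wins].sum(axis=1)
                qb = qlod5[pos, wins].sum(axis=1)
            else:
                rl = lod5[::-1][:, rc_cols]
                rq = qlod5[::-1][:, rc_cols]
                sc = rl[pos, wins].sum(axis=1)
                qb = rq[pos, wins].sum(axis=1)
            pv = table.pvalue_from_bins(qb)
            for off in np.nonzero(pv < p_threshold)[0]:
                hits.append(
                    ScanHit(locus_id, int(off), strand,
                            float(sc[off]), float(pv[off]))
                )
    return hits


def hits_to_frame(hits: list[ScanHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.locus_id, h.offset, h.strand, h.score, h.p_value) for h in hits],
        columns=["locus_id", "offset", "strand", "score", "p_value"],
    )


def motif_fraction_by_cluster(
    hits: list[ScanHit], membership: dict[str, int]
) -> dict[int, float]:
    """Per-cluster fraction of loci containing at least one motif hit.

    ``membership`` maps every scanned locus id to its cluster label; the
    denominator for a cluster is all its loci, hit or not.
    """
    hit_loci = {h.locus_id for h in hits}
    for locus in hit_loci:
        if locus not in membership:
            raise KeyError(f"hit locus {locus!r} has no cluster assignment")
    out: dict[int, float] = {}
    for cluster in sorted(set(membership.values())):
        loci = [l for l, c in membership.items() if c == cluster]
        out[cluster] = sum(l in hit_loci for l in loci) / len(loci)
    return out


def ks_overrepresentation(
    scores_pos, scores_neg, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test for score over-representation.

    ``alternative='pos_higher'`` tests the one-sided hypothesis that the
    positive scores are stochastically larger (their empirical CDF lies
    below the negative one).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    alt = {"two-sided": "two-sided", "pos_higher": "less"}[alternative]
    res = stats.ks_2samp(pos, neg, alternative=alt)
    return float(res.statistic), float(res.pvalue)
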