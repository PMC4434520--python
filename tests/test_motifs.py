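"""PWM scoring, AUC, annealing moves, exact scan p-values, KS comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats

from chipsig.motifs import (
    PWM,
    anneal_discriminative_motif,
    auc,
    best_site_score,
    encode_sequence,
    ks_overrepresentation,
    log_odds,
    motif_fraction_by_cluster,
    propose_move,
    pwm_alignment_correlation,
    random_pwm,
    reverse_complement,
    scan_sequences,
    score_pvalue_table,
)


class TestPWM:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PWM(np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_consensus_and_rc(self):
        pwm = PWM.from_consensus("ACGT", 0.9)
        assert pwm.consensus == "ACGT"
        assert pwm.reverse_complement().consensus == "ACGT"
        pwm = PWM.from_consensus("AAGG", 0.9)
        assert pwm.reverse_complement().consensus == "CCTT"

    def test_meme_roundtrip(self, tmp_path):
        pwm = random_pwm(6, np.random.default_rng(0),
                         background=np.array([0.3, 0.2, 0.2, 0.3]))
        pwm.to_meme(tmp_path / "m.meme")
        back = PWM.from_meme(tmp_path / "m.meme")
        assert np.allclose(back.probs, pwm.probs, atol=1e-6)
        assert np.allclose(back.background, pwm.background, atol=1e-5)


class TestLogOdds:
    def test_background_pwm_scores_zero(self):
        pwm = PWM(np.full((4, 4), 0.25), pseudocount=0.0)
        assert np.allclose(log_odds(pwm), 0.0)

    def test_twofold_enrichment_is_one_bit(self):
        pwm = PWM(np.array([[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]]),
                  pseudocount=0.0)
        assert log_odds(pwm)[0, 0] == pytest.approx(1.0)

    def test_hand_computed_width2(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.4, 0.1]])
        pwm = PWM(probs, pseudocount=0.01)
        adj = (probs + 0.01) / 1.04
        assert np.allclose(log_odds(pwm), np.log2(adj / 0.25))


class TestBestSiteScore:
    def test_consensus_scores_sum_of_max(self):
        pwm = PWM.from_consensus("ACGTAC", 0.9)
        lod = log_odds(pwm)
        assert best_site_score(pwm, "ACGTAC") == pytest.approx(
            lod.max(axis=1).sum()
        )

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(5, rng)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            assert best_site_score(pwm, seq) == pytest.approx(
                best_site_score(pwm, reverse_complement(seq))
            )

    def test_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(4, rng)
        lod = log_odds(pwm)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGTN"), size=20))
            best = -np.inf
            for s in (seq, reverse_complement(seq)):
                idx = encode_sequence(s)
                for off in range(len(s) - 4 + 1):
                    sc = sum(
                        lod[i, b] if (b := idx[off + i]) < 4 else 0.0
                        for i in range(4)
                    )
                    best = max(best, sc)
            assert best_site_score(pwm, seq) == pytest.approx(best)

    def test_too_short_sequence_rejected(self):
        pwm = random_pwm(8, np.random.default_rng(0))
        with pytest.raises(ValueError):
            best_site_score(pwm, "ACGT")


class TestAUC:
    @pytest.mark.parametrize(
        "pos,neg,expect",
        [([2, 3], [0, 1], 1.0), ([1], [1], 0.5), ([3, 0], [1, 2], 0.5)],
    )
    def test_examples(self, pos, neg, expect):
        assert auc(pos, neg) == pytest.approx(expect)

    def test_matches_pairwise_count(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, 5, 40).astype(float)
        neg = rng.integers(0, 5, 60).astype(float)
        brute = np.mean(
            [
                1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg
            ]
        )
        assert auc(pos, neg) == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestProposeMove:
    def test_rows_remain_distributions(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(6, rng)
        for _ in range(50):
            prop, j, _ = propose_move(pwm, rng, 20.0)
            assert np.allclose(prop.probs.sum(axis=1), 1.0, atol=1e-9)
            # only one column changed
            changed = np.nonzero(
                np.abs(prop.probs - pwm.probs).sum(axis=1) > 1e-12
            )[0]
            assert changed.tolist() == [j]

    def test_high_concentration_approaches_identity(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(4, rng)
        prop, j, _ = propose_move(pwm, rng, 1e7)
        assert np.allclose(prop.probs[j], pwm.probs[j], atol=1e-2)

    def test_column_choice_uniform(self):
        rng = np.random.default_rng(6)
        pwm = random_pwm(5, rng)
        counts = np.zeros(5)
        for _ in range(10_000):
            _, j, _ = propose_move(pwm, rng, 20.0)
            counts[j] += 1
        chi2, p = stats.chisquare(counts)
        assert p > 0.01


class TestAnneal:
    def _seqs(self, rng, n, length=60):
        return ["".join(rng.choice(list("ACGT"), size=length))
                for _ in range(n)]

    def test_zero_steps_returns_initial_random_pwm(self):
        rng = np.random.default_rng(7)
        pos, neg = self._seqs(rng, 10), self._seqs(rng, 10)
        res = anneal_discriminative_motif(
            pos, neg, width=6, schedule=(0.02, 0.999, 0), seed=3
        )
        init = random_pwm(6, np.random.default_rng(3))
        assert np.allclose(res.pwm.probs, init.probs)
        assert len(res.trace) == 1

    def test_no_signal_gives_auc_near_half(self):
        rng = np.random.default_rng(8)
        seqs = self._seqs(rng, 100, length=40)
        res = anneal_discriminative_motif(
            seqs, list(seqs), width=6, schedule=(0.01, 0.999, 300), seed=0
        )
        assert res.best_auc == pytest.approx(0.5, abs=0.05)

    def test_best_auc_trace_nondecreasing(self):
        rng = np.random.default_rng(9)
        pos, neg = self._seqs(rng, 20), self._seqs(rng, 20)
        res = anneal_discriminative_motif(
            pos, neg, width=6, schedule=(0.02, 0.999, 500), seed=1
        )
        assert np.all(np.diff(res.trace["best_auc"]) >= 0)
        assert res.best_auc >= res.trace["best_auc"].iloc[0]

    def test_near_zero_temperature_is_greedy(self):
        rng = np.random.default_rng(10)
        pos, neg = self._seqs(rng, 20), self._seqs(rng, 20)
        res = anneal_discriminative_motif(
            pos, neg, width=5, schedule=(1e-9, 1.0, 400), seed=2,
            shift_prob=0.0,
        )
        # accepted moves never lower the objective
        assert np.all(np.diff(res.trace["current_auc"]) >= -1e-12)

    def test_bad_schedule_rejected(self):
        rng = np.random.default_rng(11)
        pos, neg = self._seqs(rng, 5), self._seqs(rng, 5)
        with pytest.raises(ValueError):
            anneal_discriminative_motif(pos, neg, 6, (0.0, 0.999, 10))
        with pytest.raises(ValueError):
            anneal_discriminative_motif(pos, neg, 6, (0.01, 1.5, 10))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(12)
        pos, neg = self._seqs(rng, 15), self._seqs(rng, 15)
        a = anneal_discriminative_motif(pos, neg, 6, (0.02, 0.999, 200), seed=5)
        b = anneal_discriminative_motif(pos, neg, 6, (0.02, 0.999, 200), seed=5)
        assert np.array_equal(a.pwm.probs, b.pwm.probs)
        assert a.best_auc == b.best_auc


class TestAlignmentCorrelation:
    def test_self_and_rc_alignment_is_perfect(self):
        pwm = PWM.from_consensus("AGGAAGTG", 0.85)
        assert pwm_alignment_correlation(pwm, pwm) == pytest.approx(1.0)
        assert pwm_alignment_correlation(
            pwm.reverse_complement(), pwm
        ) == pytest.approx(1.0)

    def test_shifted_core_found_by_partial_overlap(self):
        ref = PWM.from_consensus("AGGAAGTG", 0.85)
        shifted = PWM.from_consensus("GGAAGTGC", 0.85)  # core shifted by one
        assert pwm_alignment_correlation(shifted, ref) > 0.95


class TestScorePvalueTable:
    def test_background_pwm_tail_is_one_at_zero(self):
        pwm = PWM(np.full((5, 4), 0.25), pseudocount=0.0)
        table = score_pvalue_table(pwm)
        assert table.pvalue(0.0) == pytest.approx(1.0)

    def test_width1_matches_base_distribution(self):
        pwm = PWM(np.array([[0.4, 0.3, 0.2, 0.1]]), pseudocount=0.0)
        table = score_pvalue_table(pwm, granularity=0.001)
        lod = log_odds(pwm)[0]
        order = np.argsort(lod)[::-1]
        cum = 0.0
        for b in order:
            cum += 0.25
            assert table.pvalue(lod[b]) == pytest.approx(cum, abs=1e-9)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_word_enumeration(self, width):
        pwm = random_pwm(width, np.random.default_rng(width))
        table = score_pvalue_table(pwm, granularity=0.01)
        q = table.qlod
        word_bins = {}
        for word in itertools.product(range(4), repeat=width):
            s = int(sum(q[i, b] for i, b in enumerate(word)))
            word_bins[s] = word_bins.get(s, 0.0) + 0.25**width
        for s in sorted(word_bins):
            tail = sum(p for t, p in word_bins.items() if t >= s)
            assert table.pvalue_from_bins([s])[0] == pytest.approx(
                tail, abs=1e-12
            )

    def test_tail_monotone_nonincreasing(self):
        pwm = random_pwm(7, np.random.default_rng(13))
        table = score_pvalue_table(pwm)
        assert np.all(np.diff(table.tail) <= 1e-15)


class TestScan:
    def test_threshold_one_reports_every_window(self):
        rng = np.random.default_rng(14)
        pwm = random_pwm(5, rng)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        hits = scan_sequences(pwm, [("s", seq)], p_threshold=1.01)
        assert len(hits) == 2 * (30 - 5 + 1)

    def test_planted_consensus_found_at_offsets(self):
        rng = np.random.default_rng(15)
        pwm = PWM.from_consensus("AGGAAGTG", 0.85)
        seq = list("".join(rng.choice(list("ACGT"), size=300)))
        for off in (40, 150, 260):
            seq[off:off + 8] = list("AGGAAGTG")
        hits = scan_sequences(pwm, [("s", "".join(seq))], p_threshold=1e-4)
        fwd = {h.offset for h in hits if h.strand == "+"}
        assert {40, 150, 260} <= fwd

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(16)
        pwm = PWM.from_consensus("AGGAAGTG", 0.85)
        seq = list("".join(rng.choice(list("ACGT"), size=120)))
        seq[30:38] = list("AGGAAGTG")
        seq = "".join(seq)
        fwd_hits = scan_sequences(pwm, [("s", seq)], 1e-4)
        rc_hits = scan_sequences(pwm, [("s", reverse_complement(seq))], 1e-4)
        L, w = len(seq), pwm.width
        mirrored = {
            (L - w - h.offset, "-" if h.strand == "+" else "+")
            for h in rc_hits
        }
        assert {(h.offset, h.strand) for h in fwd_hits} == mirrored

    def test_fraction_by_cluster(self):
        hits = scan_sequences(
            PWM.from_consensus("AGGAAGTG", 0.85),
            [("a", "C" * 40 + "AGGAAGTG" + "C" * 40), ("b", "C" * 90)],
            1e-4,
        )
        fr = motif_fraction_by_cluster(hits, {"a": 1, "b": 1, "c": 2})
        assert fr == {1: 0.5, 2: 0.0}


class TestKS:
    def test_identical_samples(self):
        x = np.arange(20.0)
        d, p = ks_overrepresentation(x, x)
        assert d == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_overrepresentation([5.0, 6.0, 7.0], [1.0, 2.0])
        assert d == pytest.approx(1.0)

    def test_matches_empirical_cdf_maximum(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        d, _ = ks_overrepresentation(a, b)
        grid = np.concatenate([a, b])
        brute = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert d == pytest.approx(brute)
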