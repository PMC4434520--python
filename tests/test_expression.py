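"""Probe dedup, blocked linear models, moderated t, dominance rule, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chipsig.expression import (
    DesignSpec,
    GeneClusterAssignment,
    assign_gene_cluster,
    assign_locus_to_gene,
    compare_cluster_shift,
    dedup_probes_by_iqr,
    estimate_variance_prior,
    fisher_cluster_association,
    fit_blocked_de,
    moderated_t,
    substantially_altered,
    t_scores_by_cluster,
)
from chipsig.intervals import GeneModel, GenomicInterval, Peak


def _probe_frame(rows, samples):
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", *samples])


class TestDedup:
    def test_largest_iqr_retained(self):
        samples = [f"s{i}" for i in range(4)]
        df = _probe_frame(
            [
                ["p1", "G", 0.0, 1.0, 2.0, 3.0],  # IQR 1.5
                ["p2", "G", 0.0, 2.0, 4.0, 6.0],  # IQR 3.0
            ],
            samples,
        )
        out = dedup_probes_by_iqr(df)
        assert out.loc["G", "probe_id"] == "p2"

    def test_single_probe_identity(self):
        samples = ["s0", "s1"]
        df = _probe_frame([["p1", "G", 1.0, 2.0]], samples)
        out = dedup_probes_by_iqr(df)
        assert out.loc["G", "probe_id"] == "p1"

    def test_iqr_tie_broken_by_probe_id(self):
        samples = [f"s{i}" for i in range(4)]
        df = _probe_frame(
            [
                ["pB", "G", 0.0, 1.0, 2.0, 3.0],
                ["pA", "G", 5.0, 6.0, 7.0, 8.0],
            ],
            samples,
        )
        assert dedup_probes_by_iqr(df).loc["G", "probe_id"] == "pA"

    def test_matches_per_gene_max_iqr_oracle(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(6)]
        rows = []
        for g in range(50):
            for p in range(int(rng.integers(1, 5))):
                rows.append(
                    [f"g{g}_p{p}", f"g{g}",
                     *rng.normal(5, 2, size=6).tolist()]
                )
        df = _probe_frame(rows, samples)
        out = dedup_probes_by_iqr(df)
        for g in range(50):
            gene = f"g{g}"
            sub = df[df.gene_id == gene]
            iqrs = {
                r.probe_id: np.percentile(
                    [getattr(r, s) for s in samples], 75
                ) - np.percentile([getattr(r, s) for s in samples], 25)
                for r in sub.itertuples()
            }
            best = min(
                (pid for pid, v in iqrs.items()
                 if v == max(iqrs.values()))
            )
            assert out.loc[gene, "probe_id"] == best


def _paired_design(n_blocks):
    samples, cond, block = [], [], []
    for b in range(n_blocks):
        samples += [f"kd{b}", f"ct{b}"]
        cond += ["knockdown", "control"]
        block += [f"b{b}", f"b{b}"]
    return DesignSpec(samples, cond, block, treatment_level="knockdown")


class TestBlockedFit:
    def test_block_without_both_conditions_rejected(self):
        with pytest.raises(ValueError, match="lacks both"):
            DesignSpec(
                ["a", "b"], ["knockdown", "control"], ["b1", "b2"]
            )

    def test_constant_paired_difference_recovered_exactly(self):
        design = _paired_design(3)
        base = np.array([5.0, 5.0, 7.0, 7.0, 6.0, 6.0])
        y = base.copy()
        y[::2] += 1.5  # knockdown columns
        expr = pd.DataFrame([y], index=["g1"], columns=design.samples)
        with pytest.warns(UserWarning, match="zero residual"):
            fit = fit_blocked_de(expr, design)
        assert fit.table.loc["g1", "log2fc"] == pytest.approx(1.5)
        assert fit.table.loc["g1", "s2"] == pytest.approx(0.0, abs=1e-16)

    def test_paired_fc_is_mean_of_per_block_differences(self):
        rng = np.random.default_rng(1)
        design = _paired_design(4)
        y = rng.normal(6, 1, size=8)
        expr = pd.DataFrame([y], index=["g1"], columns=design.samples)
        fit = fit_blocked_de(expr, design)
        diffs = [y[2 * b] - y[2 * b + 1] for b in range(4)]
        assert fit.table.loc["g1", "log2fc"] == pytest.approx(np.mean(diffs))

    def test_permuted_labels_give_zero_mean_fc(self):
        rng = np.random.default_rng(2)
        y = rng.normal(6, 1, size=8)
        fcs = []
        for _ in range(200):
            cond = []
            for b in range(4):
                pair = ["knockdown", "control"]
                if rng.random() < 0.5:
                    pair.reverse()
                cond += pair
            design = DesignSpec(
                [f"s{i}" for i in range(8)], cond,
                [f"b{i // 2}" for i in range(8)],
                treatment_level="knockdown",
            )
            expr = pd.DataFrame([y], index=["g"], columns=design.samples)
            fcs.append(fit_blocked_de(expr, design).table.loc["g", "log2fc"])
        se = np.std(fcs) / np.sqrt(len(fcs))
        assert abs(np.mean(fcs)) < 3 * se + 1e-12

    def test_singular_design_rejected(self):
        design = DesignSpec(
            ["a", "b"], ["knockdown", "control"], ["b1", "b1"]
        )
        # block indicator + treatment + only 2 samples -> 0 residual df
        expr = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            fit_blocked_de(expr, design)


class TestModeratedT:
    def _fit(self, seed=3, n_genes=400, df=6):
        rng = np.random.default_rng(seed)
        design = _paired_design(df + 3)  # df_resid = n - (blocks+1) = blocks-1
        n = len(design.samples)
        y = rng.normal(0, 0.5, size=(n_genes, n))
        expr = pd.DataFrame(
            y, index=[f"g{i}" for i in range(n_genes)],
            columns=design.samples,
        )
        return fit_blocked_de(expr, design)

    def test_d0_zero_gives_ordinary_t(self):
        fit = self._fit()
        out = moderated_t(fit, prior=(0.0, 1.0))
        tab = fit.table
        ordinary = tab["log2fc"] / (np.sqrt(tab["s2"]) * fit.stdunscaled)
        assert np.allclose(out["t"], ordinary)

    def test_d0_infinite_uses_common_variance(self):
        fit = self._fit()
        out = moderated_t(fit, prior=(np.inf, 0.25))
        expect = fit.table["log2fc"] / (0.5 * fit.stdunscaled)
        assert np.allclose(out["t"], expect)

    def test_prior_recovery_within_25_percent(self):
        rng = np.random.default_rng(4)
        d0_true, s0_true = 8.0, 0.09
        n_genes, df = 1000, 6
        # s2 ~ s0^2 * chi2_df-scaled draws from the prior-compound model
        prior_var = d0_true * s0_true / stats.chi2.rvs(
            d0_true, size=n_genes, random_state=rng
        )
        s2 = prior_var * stats.chi2.rvs(
            df, size=n_genes, random_state=rng
        ) / df
        d0_hat, s0_hat = estimate_variance_prior(s2, df)
        assert abs(d0_hat - d0_true) / d0_true < 0.25
        assert abs(s0_hat - s0_true) / s0_true < 0.25

    def test_moderation_shrinks_extreme_variances(self):
        fit = self._fit()
        out = moderated_t(fit)
        assert out.attrs["d0"] > 0
        spread_raw = np.log(fit.table["s2"]).std()
        spread_post = np.log(out["s2_post"]).std()
        assert spread_post < spread_raw


def _tss_gene(gid, tss, chrom="chr1"):
    return GeneModel(
        gid, chrom, "+", tss,
        exons=[GenomicInterval(chrom, tss, tss + 1000)],
    )


def _peak(name, summit, chrom="chr1"):
    return Peak(
        GenomicInterval(chrom, summit - 100, summit + 101), summit, 1.0, name
    )


class TestLocusGeneAssignment:
    def test_summit_at_tss(self):
        genes = [_tss_gene("gA", 5000), _tss_gene("gB", 9000)]
        out = assign_locus_to_gene([_peak("L", 5000)], genes)
        assert out == {"L": "gA"}

    def test_equidistant_tie_takes_smaller_gene_id(self):
        genes = [_tss_gene("gB", 4000), _tss_gene("gA", 6000)]
        out = assign_locus_to_gene([_peak("L", 5000)], genes)
        assert out == {"L": "gA"}

    def test_chromosome_without_genes_reported(self):
        genes = [_tss_gene("gA", 5000)]
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_locus_to_gene(
                [_peak("L", 5000, chrom="chr9")], genes
            )
        assert out == {}

    def test_matches_exhaustive_nearest_search(self):
        rng = np.random.default_rng(5)
        genes = [
            _tss_gene(f"g{i:03d}", int(rng.integers(0, 500_000)))
            for i in range(80)
        ]
        loci = [
            _peak(f"L{i}", int(rng.integers(200, 499_000)))
            for i in range(500)
        ]
        out = assign_locus_to_gene(loci, genes)
        for p in loci:
            best = min(
                genes, key=lambda g: (abs(g.tss - p.summit), g.gene_id)
            )
            assert out[p.name] == best.gene_id


class TestDominanceRule:
    def test_every_subset_containing_cluster1_maps_to_1(self):
        clusters = (1, 2, 3)
        for r in range(1, 4):
            for subset in itertools.combinations(clusters, r):
                locus_gene = {f"L{c}": "G" for c in subset}
                locus_cluster = {f"L{c}": c for c in subset}
                (a,) = assign_gene_cluster(locus_gene, locus_cluster)
                expect = 1 if 1 in subset else min(subset)
                assert a.cluster == expect

    def test_supporting_loci_recorded(self):
        (a,) = assign_gene_cluster(
            {"L1": "G", "L2": "G"}, {"L1": 2, "L2": 3}
        )
        assert a.cluster == 2 and a.supporting_loci == ["L1", "L2"]

    def test_missing_cluster_raises(self):
        with pytest.raises(KeyError):
            assign_gene_cluster({"L": "G"}, {})


class TestShiftAndAlteration:
    def test_identical_groups_no_shift(self):
        x = np.arange(10.0)
        stat, p = compare_cluster_shift(x, x)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_unit_shift_statistic_closed_form(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1, 1, 1000)
        b = rng.normal(0, 1, 1000)
        stat, _ = compare_cluster_shift(a, b)
        assert stat == pytest.approx(np.sqrt(1000 / 2), rel=0.1)

    def test_weighted_cluster_means_recover_global_mean(self):
        rng = np.random.default_rng(7)
        de = pd.DataFrame(
            {"t": rng.normal(size=200)},
            index=[f"g{i}" for i in range(200)],
        )
        asg = [
            GeneClusterAssignment(f"g{i}", int(rng.integers(1, 4)))
            for i in range(200)
        ]
        groups = t_scores_by_cluster(de, asg)
        total = sum(g.sum() for g in groups.values())
        count = sum(g.size for g in groups.values())
        assert total / count == pytest.approx(de["t"].mean())

    @pytest.mark.parametrize(
        "fc,p,abs_fc,expect",
        [
            (1.5, 0.005, False, True),
            (1.5, 0.02, False, False),
            (-1.5, 0.001, False, False),
            (-1.5, 0.001, True, True),
        ],
    )
    def test_substantially_altered_semantics(self, fc, p, abs_fc, expect):
        de = pd.DataFrame({"log2fc": [fc], "p": [p]}, index=["g"])
        assert substantially_altered(de, abs_fc=abs_fc).loc["g"] == expect


class TestFisher:
    def _run(self, table):
        (a, b), (c, d) = table
        asg = (
            [GeneClusterAssignment(f"x{i}", 1) for i in range(a + b)]
            + [GeneClusterAssignment(f"y{i}", 2) for i in range(c + d)]
        )
        altered = pd.Series(
            {f"x{i}": i < a for i in range(a + b)}
            | {f"y{i}": i < c for i in range(c + d)}
        )
        return fisher_cluster_association(asg, altered, cluster_ref=2)

    def test_balanced_table(self):
        odds, p, table = self._run([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0) and p == pytest.approx(1.0)
        assert table.tolist() == [[5, 5], [5, 5]]

    def test_enumerated_example(self):
        _, p, _ = self._run([[3, 1], [1, 3]])
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_matches_hypergeometric_enumeration_small_margins(self):
        for r1, r2, c1 in itertools.product(range(1, 7), range(1, 7),
                                            range(1, 9)):
            n = r1 + r2
            if c1 > n:
                continue
            lo, hi = max(0, c1 - r2), min(r1, c1)
            supp = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(supp, n, r1, c1)
            for i, a in enumerate(supp):
                table = [[int(a), r1 - int(a)],
                         [c1 - int(a), r2 - (c1 - int(a))]]
                _, p, _ = self._run(table)
                expect = pmf[pmf <= pmf[i] * (1 + 1e-7)].sum()
                assert p == pytest.approx(expect, abs=1e-9)

    def test_planted_enrichment_decreases_p(self):
        rng = np.random.default_rng(8)
        medians = []
        for enrich in (0.1, 0.3, 0.5):
            ps = []
            for _ in range(30):
                a = rng.binomial(40, enrich)
                c = rng.binomial(80, 0.1)
                _, p, _ = self._run([[a, 40 - a], [c, 80 - c]])
                ps.append(p)
            medians.append(np.median(ps))
        assert medians[0] > medians[1] > medians[2]
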