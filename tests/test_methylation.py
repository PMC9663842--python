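"""Smoothing, beta-binomial dispersion, DML Wald test, DMR calling rules."""

import numpy as np
import pandas as pd
import pytest

from perifat import methylation as me
from perifat.genomic import GeneModel, GenomicInterval
from perifat.simulate import SimulationConfig, simulate_experiment

from .conftest import make_calls


def two_sample_sexes():
    return pd.Series({"m1": "M", "f1": "F"})


class TestSmoothing:
    def test_isolated_site_is_own_fraction(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (3, 10), "f1": (8, 10)})], ["m1", "f1"]
        )
        sm = me.smooth_methylation(calls, two_sample_sexes())
        assert sm["mu_M"].iloc[0] == pytest.approx(0.3)
        assert sm["mu_F"].iloc[0] == pytest.approx(0.8)

    def test_two_close_sites_average(self):
        calls = make_calls(
            [
                ("1", 100, "CG", {"m1": (2, 10), "f1": (2, 10)}),
                ("1", 200, "CG", {"m1": (8, 10), "f1": (8, 10)}),
            ],
            ["m1", "f1"],
        )
        sm = me.smooth_methylation(calls, two_sample_sexes(), window_bp=500)
        assert np.allclose(sm["mu_M"], 0.5)

    def test_zero_window_is_identity(self):
        calls = make_calls(
            [
                ("1", 100, "CG", {"m1": (2, 10), "f1": (0, 10)}),
                ("1", 120, "CG", {"m1": (10, 10), "f1": (10, 10)}),
            ],
            ["m1", "f1"],
        )
        sm = me.smooth_methylation(calls, two_sample_sexes(), window_bp=0)
        assert sm["mu_M"].iloc[0] == pytest.approx(0.2)
        assert sm["mu_M"].iloc[1] == pytest.approx(1.0)

    def test_different_contexts_not_pooled(self):
        calls = make_calls(
            [
                ("1", 100, "CG", {"m1": (0, 10), "f1": (0, 10)}),
                ("1", 110, "CHH", {"m1": (10, 10), "f1": (10, 10)}),
            ],
            ["m1", "f1"],
        )
        sm = me.smooth_methylation(calls, two_sample_sexes(), window_bp=500)
        assert sm["mu_M"].iloc[0] == pytest.approx(0.0)
        assert sm["mu_M"].iloc[1] == pytest.approx(1.0)

    def test_zero_coverage_window_missing(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (0, 0), "f1": (3, 10)})], ["m1", "f1"]
        )
        sm = me.smooth_methylation(calls, two_sample_sexes())
        assert np.isnan(sm["mu_M"].iloc[0])


class TestSiteDispersion:
    def _sim_calls(self, rng, phi, mu=0.5, coverage=30, n_per_sex=100):
        samples = [f"m{i}" for i in range(n_per_sex)] + [
            f"f{i}" for i in range(n_per_sex)
        ]
        per_sample = {}
        for s in samples:
            if phi > 0:
                a = mu * (1 - phi) / phi
                b = (1 - mu) * (1 - phi) / phi
                p = rng.beta(a, b)
            else:
                p = mu
            per_sample[s] = (int(rng.binomial(coverage, p)), coverage)
        calls = make_calls([("1", 100, "CG", per_sample)], samples)
        sexes = pd.Series(
            ["M"] * n_per_sex + ["F"] * n_per_sex, index=samples
        )
        return calls, sexes

    def test_binomial_site_near_floor(self, rng):
        calls, sexes = self._sim_calls(rng, phi=0.0)
        phi = me.estimate_site_dispersion(calls, sexes)
        assert phi[0] < 0.02

    def test_recovery_of_planted_phi(self, rng):
        est = []
        for _ in range(10):
            calls, sexes = self._sim_calls(rng, phi=0.2)
            est.append(me.estimate_site_dispersion(calls, sexes)[0])
        assert np.mean(est) == pytest.approx(0.2, abs=0.07)

    def test_single_covered_sample_floor(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (3, 10), "f1": (0, 0)})], ["m1", "f1"]
        )
        phi = me.estimate_site_dispersion(calls, two_sample_sexes())
        assert phi[0] == me.PHI_FLOOR


class TestWaldDml:
    def test_equal_groups_null(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (5, 10), "f1": (5, 10)})], ["m1", "f1"]
        )
        res = me.DifferentialMethylation(calls, two_sample_sexes()).fit()
        assert res.table["wald_stat"].iloc[0] == 0.0
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_uncovered_sex_skipped(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (0, 0), "f1": (5, 10)})], ["m1", "f1"]
        )
        res = me.DifferentialMethylation(calls, two_sample_sexes()).fit()
        assert len(res.table) == 0
        assert res.n_skipped == 1

    def test_power_at_planted_delta(self):
        """Planted delta 0.5 at 30x coverage, 6 vs 6 -> p < 0.001 for >=95%
        of sites."""
        cfg = SimulationConfig(
            n_genes=50,
            n_sites={"CG": 1200, "CHG": 50, "CHH": 50},
            dmr_count=40,
            dmr_delta_range=(0.5, 0.5),
            dmr_length_range=(150, 250),
            coverage_mean=30,
            de_fraction=0.0,
            module_spec=[],
            trait_spec={},
            seed=41,
        )
        _, calls, _, _, meta, truth = simulate_experiment(cfg)
        res = me.DifferentialMethylation(calls, meta.sexes).fit()
        t = res.table
        hits = []
        for _, d in truth.true_dmrs.iterrows():
            mask = (
                (t["chrom"] == d["chrom"])
                & (t["pos"] >= d["start"])
                & (t["pos"] <= d["end"])
            )
            hits.extend(t.loc[mask, "p_value"] < 0.001)
        assert np.mean(hits) >= 0.95

    def test_type_one_error_in_band(self):
        cfg = SimulationConfig(
            n_genes=50,
            n_sites={"CG": 2000, "CHG": 500, "CHH": 500},
            dmr_count=0,
            de_fraction=0.0,
            module_spec=[],
            trait_spec={},
            seed=42,
        )
        _, calls, _, _, meta, _ = simulate_experiment(cfg)
        res = me.DifferentialMethylation(calls, meta.sexes).fit()
        frac = (res.table["p_value"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08


def dml_frame(rows):
    """rows of (chrom, pos, context, p, mu_f, mu_m)."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "context", "p_value", "mu_f", "mu_m"]
    )


class TestCallDmrs:
    def test_hand_traced_region(self):
        rows = [("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 130, 160)]
        rows += [("1", p, "CG", 0.9, 0.5, 0.5) for p in (5000, 6000, 7000)]
        dmrs = me.call_dmrs(dml_frame(rows))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.interval.start, d.interval.end) == (100, 160)
        assert d.length == 61
        assert d.n_sites == 3
        assert d.n_significant == 3

    def test_min_length_boundary(self):
        kept = me.call_dmrs(
            dml_frame([("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 120, 149)])
        )
        assert len(kept) == 1 and kept[0].length == 50
        rejected = me.call_dmrs(
            dml_frame([("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 120, 148)])
        )
        assert rejected == []

    def test_merge_gap_boundary(self):
        # regions 100-160 and 200-260: gap = 200 - 160 - 1 = 39 < 50 -> merge
        close = [("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 130, 160, 200, 230, 260)]
        dmrs = me.call_dmrs(dml_frame(close), cluster_gap=39)
        assert len(dmrs) == 1
        assert (dmrs[0].interval.start, dmrs[0].interval.end) == (100, 260)
        assert dmrs[0].n_sites == 6
        # gap = 216 - 160 - 1 = 55 >= 50 -> kept apart
        apart = [("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 130, 160, 216, 246, 276)]
        dmrs = me.call_dmrs(dml_frame(apart), cluster_gap=40)
        assert len(dmrs) == 2

    def test_significant_fraction_rule(self):
        # 3 candidates + 4 non-significant sites in span -> 3/7 < 0.5 -> reject
        rows = [("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 150, 200)]
        rows += [("1", p, "CG", 0.5, 0.5, 0.5) for p in (110, 120, 130, 140)]
        assert me.call_dmrs(dml_frame(rows)) == []

    def test_contexts_processed_independently(self):
        rows = [("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 130)]
        rows += [("1", 160, "CHH", 0.001, 0.8, 0.3)]
        assert me.call_dmrs(dml_frame(rows)) == []

    def test_deterministic(self):
        rows = [("1", p, "CG", 0.001, 0.8, 0.3) for p in (100, 130, 160)]
        assert me.call_dmrs(dml_frame(rows)) == me.call_dmrs(dml_frame(rows))


class TestAnnotation:
    @pytest.fixture
    def gene_models(self):
        return [
            GeneModel(
                "GA",
                GenomicInterval("1", 10_000, 20_000, "+"),
                [
                    GenomicInterval("1", 10_000, 12_000, "+"),
                    GenomicInterval("1", 15_000, 20_000, "+"),
                ],
            ),
            GeneModel("GB", GenomicInterval("1", 50_000, 60_000, "-")),
        ]

    def _dmr(self, start, end, chrom="1"):
        return me.Dmr(GenomicInterval(chrom, start, end), "CG", 3, 3, 0.8, 0.3)

    def test_exon_only(self, gene_models):
        d = me.annotate_genomic_context(self._dmr(11_100, 11_500), gene_models)
        assert d.genomic_context == "Exon"
        assert d.assigned_gene == "GA"
        assert d.distance_to_gene == 0

    def test_exon_intron_junction(self, gene_models):
        d = me.annotate_genomic_context(self._dmr(11_900, 12_500), gene_models)
        assert d.genomic_context == "Exon/Intron"

    def test_promoter_precedence(self, gene_models):
        d = me.annotate_genomic_context(self._dmr(9_500, 10_200), gene_models)
        assert d.genomic_context.startswith("Promoter")

    def test_minus_strand_promoter(self, gene_models):
        # GB is on '-', TSS = 60000; promoter spans 59000-61000
        d = me.annotate_genomic_context(self._dmr(60_500, 60_800), gene_models)
        assert d.genomic_context == "Promoter"
        assert d.assigned_gene == "GB"

    def test_intergenic_with_nearest_gene(self, gene_models):
        d = me.annotate_genomic_context(self._dmr(30_000, 30_100), gene_models)
        assert d.genomic_context == "Intergenic"
        assert d.assigned_gene == "GA"
        assert d.distance_to_gene == 10_000

    def test_empty_gene_set(self):
        d = me.annotate_genomic_context(self._dmr(100, 200), [])
        assert d.genomic_context == "Intergenic"
        assert d.assigned_gene is None


class TestDmrFeatures:
    def test_single_site(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (3, 10), "f1": (0, 0)})], ["m1", "f1"]
        )
        d = me.Dmr(GenomicInterval("1", 50, 150), "CG", 1, 1, 0.5, 0.5)
        vals = me.dmr_mean_methylation(calls, d)
        assert vals["m1"] == pytest.approx(0.3)
        assert np.isnan(vals["f1"])

    def test_mean_of_sites(self):
        calls = make_calls(
            [
                ("1", 100, "CG", {"m1": (2, 10), "f1": (1, 10)}),
                ("1", 110, "CG", {"m1": (4, 10), "f1": (1, 10)}),
                ("1", 120, "CG", {"m1": (9, 10), "f1": (1, 10)}),
            ],
            ["m1", "f1"],
        )
        d = me.Dmr(GenomicInterval("1", 90, 130), "CG", 3, 3, 0.5, 0.5)
        assert me.dmr_mean_methylation(calls, d)["m1"] == pytest.approx(0.5)


class TestContextSummary:
    def test_identical_sexes_zero_d(self):
        calls = make_calls(
            [
                ("1", 100, "CG", {"m1": (3, 10), "f1": (3, 10)}),
                ("1", 200, "CG", {"m1": (7, 10), "f1": (7, 10)}),
            ],
            ["m1", "f1"],
        )
        summ = me.context_summary(calls, two_sample_sexes())
        assert summ[0].cohens_d == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # means 0.6 vs 0.5, both SD computed from two sites
        calls = make_calls(
            [
                ("1", 100, "CG", {"m1": (25, 100), "f1": (35, 100)}),
                ("1", 5000, "CG", {"m1": (75, 100), "f1": (85, 100)}),
            ],
            ["m1", "f1"],
        )
        summ = me.context_summary(calls, two_sample_sexes())
        s = summ[0]
        assert s.mean_f == pytest.approx(0.6)
        assert s.mean_m == pytest.approx(0.5)
        # equal SDs -> pooled SD equals them; d = 0.1 / sd
        assert s.cohens_d == pytest.approx(0.1 / s.sd_f)

    def test_generator_baselines_recovered(self):
        """Global per-context means track the generator's baselines."""
        cfg = SimulationConfig(
            n_genes=50,
            n_sites={"CG": 1500, "CHG": 800, "CHH": 800},
            dmr_count=0,
            de_fraction=0.0,
            module_spec=[],
            trait_spec={},
            seed=43,
        )
        _, calls, _, _, meta, _ = simulate_experiment(cfg)
        summ = {s.context: s for s in me.context_summary(calls, meta.sexes)}
        for ctx, target in cfg.context_baseline_mean.items():
            assert summ[ctx].mean_m == pytest.approx(target, abs=0.04)
            assert summ[ctx].cohens_d < 0.1  # no planted sex effect


class TestDmrRecovery:
    def test_planted_dmr_sensitivity_precision(self):
        """200 bp, delta 0.4 CG DMRs at 20x coverage are recovered with
        sensitivity and precision >= 0.8 (50% reciprocal overlap)."""
        cfg = SimulationConfig(
            n_genes=100,
            n_sites={"CG": 3000, "CHG": 300, "CHH": 300},
            dmr_count=30,
            dmr_length_range=(200, 200),
            dmr_delta_range=(0.4, 0.4),
            coverage_mean=20,
            de_fraction=0.02,
            module_spec=[],
            trait_spec={},
            seed=44,
        )
        _, calls, _, _, meta, truth = simulate_experiment(cfg)
        res = me.DifferentialMethylation(calls, meta.sexes).fit()
        dmrs = res.call_dmrs()
        planted = truth.true_dmrs[truth.true_dmrs["context"] == "CG"]
        called = [d for d in dmrs if d.context == "CG"]

        def reciprocal(d, row):
            ov = max(
                0,
                min(d.interval.end, row["end"]) - max(d.interval.start, row["start"]) + 1,
            )
            return (
                d.interval.chrom == row["chrom"]
                and ov >= 0.5 * d.length
                and ov >= 0.5 * (row["end"] - row["start"] + 1)
            )

        sens = np.mean(
            [any(reciprocal(d, row) for d in called) for _, row in planted.iterrows()]
        )
        prec = np.mean(
            [any(reciprocal(d, row) for _, row in planted.iterrows()) for d in called]
        )
        assert sens >= 0.8
        assert prec >= 0.8

    def test_dmr_invariants_hold(self):
        cfg = SimulationConfig(
            n_genes=50,
            n_sites={"CG": 1500, "CHG": 200, "CHH": 200},
            dmr_count=15,
            module_spec=[],
            trait_spec={},
            seed=45,
        )
        _, calls, _, _, meta, _ = simulate_experiment(cfg)
        dmrs = me.DifferentialMethylation(calls, meta.sexes).fit().call_dmrs()
        assert dmrs
        for d in dmrs:
            assert d.length >= 50
            assert d.n_sites >= 3
            assert d.n_significant / d.n_sites >= 0.5
            assert 0 <= d.mean_meth_f <= 1 and 0 <= d.mean_meth_m <= 1


class TestCollapseCpg:
    def test_adjacent_opposite_strand_pair_merges(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (3, 10), "f1": (1, 5)}),
             ("1", 300, "CHH", {"m1": (1, 10), "f1": (1, 10)})],
            ["m1", "f1"],
        )
        minus = calls.table.iloc[[0]].copy()
        minus["pos"] = 101
        minus["strand"] = "-"
        minus["m1_meth"], minus["m1_total"] = 2, 8
        calls.table = pd.concat([calls.table, minus], ignore_index=True)
        merged = me.collapse_cpg_strands(
            type(calls)(calls.table, calls.samples)
        )
        cg = merged.table[merged.table["context"] == "CG"]
        assert len(cg) == 1
        assert int(cg["m1_meth"].iloc[0]) == 5
        assert int(cg["m1_total"].iloc[0]) == 18
        assert len(merged.table[merged.table["context"] == "CHH"]) == 1

    def test_unpaired_sites_pass_through(self):
        calls = make_calls(
            [("1", 100, "CG", {"m1": (3, 10), "f1": (1, 5)})], ["m1", "f1"]
        )
        merged = me.collapse_cpg_strands(calls)
        pd.testing.assert_frame_equal(merged.table, calls.table)
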