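import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chromrisk import simulate as sm
from chromrisk.geneassoc import (
    gene_statistic,
    overlap_counts,
    qc_sumstats,
    quadform_pvalue,
    run_gene_tests,
    top_genes,
)
from chromrisk.genome_io import GeneSnpMap, SummaryStats


def make_ss(**overrides):
    n = 10
    base = {
        "snp": [f"rs{i}" for i in range(n)],
        "chrom": ["1"] * n, "bp": np.arange(n) * 100 + 1,
        "a1": ["A"] * n, "a2": ["G"] * n,
        "z": np.linspace(-2, 2, n), "p": np.full(n, 0.5),
        "n": np.full(n, 1000.0), "info": np.ones(n), "maf": np.full(n, 0.2),
    }
    base.update(overrides)
    return SummaryStats(pd.DataFrame(base))


class TestQc:
    def test_nonpositive_se_dropped(self):
        ss = make_ss()
        ss.table["se"] = [0.1] * 9 + [0.0]
        out, report = qc_sumstats(ss)
        assert report["dropped_se"] == 1 and len(out) == 9

    def test_n_outliers_dropped(self):
        m = 50
        n = np.full(m, 1000.0)
        n[0] = 1e7
        ss = SummaryStats(pd.DataFrame({
            "snp": [f"rs{i}" for i in range(m)], "chrom": ["1"] * m,
            "bp": np.arange(m) + 1, "a1": ["A"] * m, "a2": ["G"] * m,
            "z": np.zeros(m), "p": np.full(m, 0.5), "n": n,
            "info": np.ones(m), "maf": np.full(m, 0.2)}))
        out, report = qc_sumstats(ss)
        assert report["dropped_n_outlier"] == 1
        assert "rs0" not in set(out.table["snp"])

    def test_sex_and_mito_chromosomes_dropped(self):
        chrom = ["1"] * 7 + ["X", "chrY", "MT"]
        out, report = qc_sumstats(make_ss(chrom=chrom))
        assert report["dropped_sex_mito"] == 3
        assert set(out.table["chrom"]) == {"1"}

    def test_indels_and_multiallelics_retained(self):
        ss = make_ss(a1=["AT"] * 5 + ["A"] * 5)
        out, _ = qc_sumstats(ss)
        assert len(out) == 10


class TestGeneStatistic:
    @pytest.mark.parametrize("z,expected", [
        ([2.0], 4.0), ([1.0, 1.0, 1.0], 3.0), ([0.0] * 7, 0.0)])
    def test_sum_of_squares(self, z, expected):
        assert gene_statistic(np.array(z)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_statistic(np.array([]))


class TestQuadformPvalue:
    def test_single_snp_closed_form(self):
        assert quadform_pvalue(4.0, np.eye(1)) == pytest.approx(
            stats.chi2.sf(4.0, 1), abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 10, 25, 50])
    def test_identity_ld_equals_chisq_survival(self, k):
        for T in (0.5 * k, k, 2.0 * k, 4.0 * k):
            assert quadform_pvalue(T, np.eye(k)) == pytest.approx(
                stats.chi2.sf(T, k), abs=1e-6)

    def test_perfect_ld_collapses_to_one_dof(self):
        R = np.ones((2, 2))
        assert quadform_pvalue(8.0, R) == pytest.approx(
            stats.chi2.sf(4.0, 1), abs=1e-10)

    def test_ar1_matches_monte_carlo(self):
        k, rho = 5, 0.7
        R = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        lam = np.linalg.eigvalsh(R)
        rng = np.random.default_rng(123)
        draws = (lam * rng.standard_normal((200_000, k)) ** 2).sum(axis=1)
        for T in (3.0, 8.0, 15.0):
            emp = (draws >= T).mean()
            se = np.sqrt(emp * (1 - emp) / draws.size)
            assert quadform_pvalue(T, R) == pytest.approx(emp, abs=2 * se)

    def test_monotone_decreasing_in_statistic(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 6))
        R = np.corrcoef(x, rowvar=False)
        ps = [quadform_pvalue(T, R) for T in np.linspace(0.5, 40, 25)]
        assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:]))

    def test_asymmetric_matrix_rejected(self):
        R = np.eye(3)
        R[0, 1] = 0.5
        with pytest.raises(ValueError):
            quadform_pvalue(3.0, R)


class TestRunGeneTests:
    def test_deterministic_and_bh_adjusted(self, panel, sim_cfg):
        ss, _ = sm.simulate_gwas(panel, {}, sim_cfg)
        gmap = GeneSnpMap()
        for b, (_, idx) in enumerate(
                list(panel.snps.groupby("block").groups.items())[:30]):
            for i in idx:
                gmap.add(f"G{b:03d}", panel.snps["snp"].iloc[i])
        r1 = run_gene_tests(gmap, ss, panel)
        r2 = run_gene_tests(gmap, ss, panel)
        pd.testing.assert_frame_equal(r1, r2)
        np.testing.assert_allclose(
            r1["q"], multipletests(r1["p"], method="fdr_bh")[1])
        assert (r1["q"] >= r1["p"] - 1e-12).all()

    def test_genes_without_panel_snps_skipped(self, panel, sim_cfg):
        ss, _ = sm.simulate_gwas(panel, {}, sim_cfg)
        gmap = GeneSnpMap(snps={"GHOST": ["rs_absent"],
                                "G1": [panel.snps["snp"].iloc[0]]})
        res = run_gene_tests(gmap, ss, panel)
        assert list(res["gene_id"]) == ["G1"]

    def test_enhancer_signal_found_by_loop_annotation_not_window(self):
        """A causal enhancer > 10 kb from its gene is picked up only when
        SNPs are routed through chromatin loops."""
        from chromrisk import annot as am
        from chromrisk.loops import TSS_WINDOW, _min_tss_distance

        cfg = sm.SimConfig(seed=31, n_genes=20, n_snps=1500, n_samples=500,
                           gwas_n=100_000, h2_total=0.5)
        genes, peaks, loops = sm.simulate_genome(cfg)
        panel = sm.simulate_ld_panel(cfg)
        tss = genes.tss_sites()
        enh = [p for p in peaks["h3k27ac"]
               if _min_tss_distance(p, tss) > TSS_WINDOW]
        # concentrate all heritability in SNPs inside enhancer regions
        chrom = panel.snps["chrom"].to_numpy()
        bp = panel.snps["bp"].to_numpy()
        mask = np.zeros(len(bp), dtype=bool)
        for e in enh:
            mask |= (chrom == e.chrom) & (bp >= e.start) & (bp < e.end)
        assert mask.any()
        cfg.enrichment_spec = {"enh": 1.0}
        ss, _ = sm.simulate_gwas(panel, {"enh": mask}, cfg)

        full = am.build_annotation("full", ss, genes, loops=loops,
                                   enhancers=enh)
        res_full = run_gene_tests(full, ss, panel)
        win = am.build_annotation("window10kb", ss, genes)
        res_win = run_gene_tests(win, ss, panel)
        sig_full = set(res_full.loc[res_full["significant"], "gene_id"])
        sig_win = set(res_win.loc[res_win["significant"], "gene_id"])
        assert sig_full  # loop-annotated genes detect the enhancer signal
        # enhancer-driven genes found via loops are missed by the window
        assert sig_full - sig_win


class TestTopGenesAndOverlap:
    def test_threshold_strictness(self):
        res = pd.DataFrame({"gene_id": ["A", "B"], "p": [4e-8, 1e-3]})
        assert top_genes(res, 5e-8) == {"A"}
        assert top_genes(res, 5e-12) == set()
        assert top_genes(pd.DataFrame({"gene_id": [], "p": []}), 5e-8) == set()

    def test_exclusive_counts_small_case(self):
        counts = overlap_counts({"S1": {"A", "B"}, "S2": {"B", "C"}})
        assert counts[("S1",)] == 1
        assert counts[("S2",)] == 1
        assert counts[("S1", "S2")] == 1

    def test_identical_sets_only_full_intersection(self):
        counts = overlap_counts({"a": {"X", "Y"}, "b": {"X", "Y"}})
        assert counts[("a", "b")] == 2
        assert counts[("a",)] == counts[("b",)] == 0

    def test_matches_membership_vector_tally(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(60)]
        sets = {f"S{j}": set(rng.choice(genes, rng.integers(5, 30),
                                        replace=False))
                for j in range(5)}
        counts = overlap_counts(sets)
        names = sorted(sets)
        tally = {}
        for g in set().union(*sets.values()):
            key = tuple(n for n in names if g in sets[n])
            tally[key] = tally.get(key, 0) + 1
        for key, n in tally.items():
            assert counts[key] == n
        assert sum(counts.values()) == len(set().union(*sets.values()))


class TestBenjaminiHochberg:
    def test_textbook_step_up_values(self):
        q = multipletests([0.005, 0.01, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])
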