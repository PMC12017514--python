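import numpy as np
import pandas as pd
import pytest

from chromrisk import simulate as sm
from chromrisk import sldsc as sd
from chromrisk.genome_io import SummaryStats


@pytest.fixture(scope="module")
def recovery_fit():
    """One stratified regression on data with a planted enrichment of 5."""
    cfg = sm.SimConfig(seed=42, n_snps=4000, n_samples=600, gwas_n=50_000,
                       h2_total=0.4, enrichment_spec={"A": 0.5})
    panel = sm.simulate_ld_panel(cfg)
    mask = np.zeros(4000, dtype=bool)
    mask[::10] = True  # 10% of SNPs carry 50% of h2 => enrichment 5
    ss, truth = sm.simulate_gwas(panel, {"A": mask}, cfg)
    annot = pd.DataFrame(
        {"base": 1, "A": mask.astype(int)},
        index=pd.Index(panel.snps["snp"], name="snp"))
    ld = sd.compute_ld_scores(panel, annot, window_bp=200_000)
    fit = sd.fit_sldsc(ss.table["z"].to_numpy() ** 2, ld,
                       ss.table["n"].to_numpy(), annot, n_blocks=100)
    return fit, truth


class TestBinsToAnnotations:
    def test_membership_matches_brute_force(self, genome, labels, panel):
        _, _, loops = genome
        bin_sets = sd.category_bin_sets(loops, labels)
        annot = sd.bins_to_annotations(bin_sets, panel.snps)
        assert (annot["base"] == 1).all()
        for name, bins in bin_sets.items():
            for _, row in panel.snps.iterrows():
                member = any(iv.contains(row["chrom"], int(row["bp"]))
                             for iv in bins)
                assert bool(annot.loc[row["snp"], name]) == member

    def test_category_nesting(self, genome, labels, panel):
        _, _, loops = genome
        annot = sd.bins_to_annotations(
            sd.category_bin_sets(loops, labels), panel.snps)
        # promoter and enhancer SNPs are inside total; their union is the
        # promoter_enhancer category
        assert (annot["promoter"] <= annot["total"]).all()
        assert (annot["enhancer"] <= annot["total"]).all()
        union = ((annot["promoter"] | annot["enhancer"]) > 0).astype(int)
        assert (annot["promoter_enhancer"] == union).all()


class TestLdScores:
    def test_base_score_near_one_for_independent_snps(self):
        cfg = sm.SimConfig(seed=13, n_snps=300, ld_rho=0.0, n_samples=2000)
        panel = sm.simulate_ld_panel(cfg)
        annot = pd.DataFrame({"base": np.ones(300, int)},
                             index=pd.Index(panel.snps["snp"], name="snp"))
        ld = sd.compute_ld_scores(panel, annot, window_bp=10_000_000)
        # bias-corrected r2 averages ~0 off-diagonal; self term ~1
        assert ld["base"].mean() == pytest.approx(1.0, abs=0.1)

    def test_duplicate_snp_contributes_unit_score(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal((500, 3))
        g[:, 1] = g[:, 0]  # exact duplicate column
        snps = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": "chr1",
                             "bp": [100, 200, 300], "maf": 0.3,
                             "block": [0, 0, 0]})
        panel = sm.Panel(genotypes=g, snps=snps)
        annot = pd.DataFrame({"base": [1, 1, 1]},
                             index=pd.Index(snps["snp"], name="snp"))
        ld = sd.compute_ld_scores(panel, annot, window_bp=1000)
        assert ld.loc["a", "base"] >= 1.9  # self + twin

    def test_matches_all_pairs_brute_force(self, panel):
        annot = pd.DataFrame(
            {"base": 1,
             "odd": (np.arange(panel.n_snps) % 2).astype(int)},
            index=pd.Index(panel.snps["snp"], name="snp"))
        window = 50_000
        ld = sd.compute_ld_scores(panel, annot, window_bp=window)
        n = panel.n_samples
        g = panel.genotypes
        gz = (g - g.mean(0)) / g.std(0)
        chrom = panel.snps["chrom"].to_numpy()
        bp = panel.snps["bp"].to_numpy()
        A = annot.to_numpy(float)
        for j in [0, 7, 100, panel.n_snps - 1]:
            for c, name in enumerate(annot.columns):
                expected = 0.0
                for k in range(panel.n_snps):
                    if chrom[k] != chrom[j] or abs(bp[k] - bp[j]) > window:
                        continue
                    if not A[k, c]:
                        continue
                    r2 = (gz[:, j] @ gz[:, k] / n) ** 2
                    expected += r2 - (1 - r2) / (n - 2)
                assert ld.iloc[j, c] == pytest.approx(expected, rel=1e-8)

    def test_ar1_block_matches_analytic_value(self):
        cfg = sm.SimConfig(seed=19, n_snps=500, ld_rho=0.8, ld_block_size=10,
                           n_samples=2000)
        panel = sm.simulate_ld_panel(cfg)
        annot = pd.DataFrame({"base": np.ones(500, int)},
                             index=pd.Index(panel.snps["snp"], name="snp"))
        ld = sd.compute_ld_scores(panel, annot, window_bp=10_000_000)
        # middle SNP of an AR(1) block: l = sum_d rho^(2|d|) over the block
        rho2 = 0.8 ** 2
        mids = [i for i in range(500) if i % 10 == 5]
        expect = sum(rho2 ** abs(d - 5) for d in range(10))
        assert np.mean(ld["base"].iloc[mids]) == pytest.approx(expect, rel=0.05)

    def test_tiny_panel_rejected(self):
        snps = pd.DataFrame({"snp": ["a"], "chrom": "chr1", "bp": [1],
                             "maf": 0.2, "block": [0]})
        panel = sm.Panel(np.zeros((2, 1)), snps)
        annot = pd.DataFrame({"base": [1]}, index=pd.Index(["a"], name="snp"))
        with pytest.raises(ValueError):
            sd.compute_ld_scores(panel, annot)


class TestMunge:
    def _ss(self, **overrides):
        n = 8
        base = {
            "snp": [f"rs{i}" for i in range(n)], "chrom": ["1"] * n,
            "bp": np.arange(n) + 1, "a1": ["A"] * n, "a2": ["G"] * n,
            "z": np.ones(n), "p": np.full(n, 0.3), "n": np.full(n, 1e4),
            "info": np.ones(n), "maf": np.full(n, 0.2)}
        base.update(overrides)
        return SummaryStats(pd.DataFrame(base))

    def test_info_filter(self):
        out, rep = sd.munge_for_ldsc(self._ss(info=[0.85] + [0.95] * 7))
        assert rep["dropped_info"] == 1 and len(out) == 7

    def test_maf_filter(self):
        out, rep = sd.munge_for_ldsc(self._ss(maf=[0.005] + [0.2] * 7))
        assert rep["dropped_maf"] == 1

    def test_strand_ambiguous_dropped(self):
        out, rep = sd.munge_for_ldsc(
            self._ss(a1=["A", "C", "A", "A", "A", "A", "A", "A"],
                     a2=["T", "G", "G", "G", "G", "G", "G", "G"]))
        assert rep["dropped_ambiguous"] == 2
        assert set(out.table["snp"]) == {f"rs{i}" for i in range(2, 8)}

    def test_duplicates_and_keep_list(self):
        ss = self._ss(snp=["rs0", "rs0", "rs2", "rs3", "rs4", "rs5", "rs6",
                           "rs7"])
        out, rep = sd.munge_for_ldsc(ss, keep_snps={"rs2", "rs3", "rs4"})
        assert rep["dropped_duplicate_id"] == 2
        assert set(out.table["snp"]) == {"rs2", "rs3", "rs4"}

    def test_passing_record_kept(self):
        out, _ = sd.munge_for_ldsc(self._ss(maf=np.full(8, 0.02),
                                            info=np.full(8, 0.95)))
        assert len(out) == 8


class TestFit:
    def test_enrichment_recovery_ci_covers_truth(self, recovery_fit):
        fit, truth = recovery_fit
        row = fit.table.loc["A"]
        assert truth.enrichment["A"] == pytest.approx(5.0)
        assert row["enrichment_ci_lo"] <= 5.0 <= row["enrichment_ci_hi"]
        assert row["tau_z"] > 2  # strong positive coefficient

    def test_h2_total_recovered(self, recovery_fit):
        fit, _ = recovery_fit
        assert fit.h2_total == pytest.approx(0.4, rel=0.5)

    def test_null_model_intercept_and_coefficients(self):
        """Without heritability the regression sees intercept 1 (averaged
        over seeds; a single intercept is noisy) and null coefficients."""
        intercepts = []
        for seed in range(5):
            cfg = sm.SimConfig(seed=23 + seed, n_snps=2000, n_samples=400,
                               h2_total=0.0)
            panel = sm.simulate_ld_panel(cfg)
            ss, _ = sm.simulate_gwas(panel, {}, cfg)
            annot = pd.DataFrame(
                {"base": 1,
                 "A": (np.arange(2000) % 7 == 0).astype(int)},
                index=pd.Index(panel.snps["snp"], name="snp"))
            ld = sd.compute_ld_scores(panel, annot, window_bp=200_000)
            fit = sd.fit_sldsc(ss.table["z"].to_numpy() ** 2, ld,
                               ss.table["n"].to_numpy(), annot, n_blocks=50)
            intercepts.append(fit.intercept)
            for name in ("base", "A"):
                r = fit.table.loc[name]
                assert abs(r["tau"]) <= 3.5 * r["tau_se"]
        assert np.mean(intercepts) == pytest.approx(1.0, abs=0.45)

    def test_proportions_sum_to_one_for_disjoint_exhaustive(self):
        cfg = sm.SimConfig(seed=29, n_snps=1000, n_samples=400, h2_total=0.3,
                           enrichment_spec={"left": 0.7})
        panel = sm.simulate_ld_panel(cfg)
        left = np.zeros(1000, dtype=bool)
        left[:500] = True
        ss, _ = sm.simulate_gwas(panel, {"left": left}, cfg)
        annot = pd.DataFrame(
            {"base": 1, "left": left.astype(int),
             "right": (~left).astype(int)},
            index=pd.Index(panel.snps["snp"], name="snp"))
        ld = sd.compute_ld_scores(panel, annot, window_bp=100_000)
        # left/right partition the genome exhaustively, so the base column
        # is their exact sum and must be excluded from the design
        fit = sd.fit_sldsc(ss.table["z"].to_numpy() ** 2, ld,
                           ss.table["n"].to_numpy(), annot, n_blocks=40,
                           include_base=False)
        assert fit.table.loc["left", "prop_h2"] \
            + fit.table.loc["right", "prop_h2"] == pytest.approx(1.0, abs=1e-6)

    def test_too_many_blocks_rejected(self, recovery_fit):
        cfg = sm.SimConfig(seed=1, n_snps=100, n_samples=100)
        panel = sm.simulate_ld_panel(cfg)
        ss, _ = sm.simulate_gwas(panel, {}, cfg)
        annot = pd.DataFrame({"base": np.ones(100, int)},
                             index=pd.Index(panel.snps["snp"], name="snp"))
        ld = sd.compute_ld_scores(panel, annot, window_bp=100_000)
        with pytest.raises(ValueError):
            sd.fit_sldsc(ss.table["z"].to_numpy() ** 2, ld,
                         ss.table["n"].to_numpy(), annot, n_blocks=101)

    def test_collinear_annotations_named(self):
        cfg = sm.SimConfig(seed=1, n_snps=200, n_samples=100)
        panel = sm.simulate_ld_panel(cfg)
        ss, _ = sm.simulate_gwas(panel, {}, cfg)
        dup = (np.arange(200) % 2).astype(int)
        annot = pd.DataFrame({"base": 1, "A": dup, "B": dup},
                             index=pd.Index(panel.snps["snp"], name="snp"))
        ld = sd.compute_ld_scores(panel, annot, window_bp=100_000)
        with pytest.raises(ValueError, match="collinear"):
            sd.fit_sldsc(ss.table["z"].to_numpy() ** 2, ld,
                         ss.table["n"].to_numpy(), annot, n_blocks=20)


class TestHeatmapTable:
    def _fit(self, enrichment_p, tau_z):
        table = pd.DataFrame({
            "tau": [1e-5, 1e-4], "tau_se": [1e-5, 1e-4],
            "tau_z": [1.0, tau_z], "prop_h2": [1.0, 0.5],
            "prop_h2_se": [0.1, 0.1], "prop_snps": [1.0, 0.1],
            "enrichment": [1.0, 5.0], "enrichment_se": [0.0, 1.0],
            "enrichment_ci_lo": [1.0, 3.0], "enrichment_ci_hi": [1.0, 7.0],
            "enrichment_p": [1.0, enrichment_p],
        }, index=pd.Index(["base", "cat"], name="annotation"))
        return sd.SldscFit(table=table, intercept=1.0, h2_total=0.3)

    def test_log_arithmetic_and_bh_across_grid(self):
        fits = {("AD", "microglia"): self._fit(0.01, 3.0)}
        out = sd.enrichment_heatmap_table(fits)
        assert len(out) == 1  # base excluded
        assert out["neg_log10_q"].iloc[0] == pytest.approx(2.0)

    def test_negative_coefficient_zeroed(self):
        fits = {("AD", "microglia"): self._fit(0.001, -1.0)}
        out = sd.enrichment_heatmap_table(fits)
        assert out["neg_log10_q"].iloc[0] == 0.0

    def test_grid_bh_recomputed_across_all_rows(self):
        fits = {("AD", "mg"): self._fit(0.01, 2.0),
                ("PD", "mg"): self._fit(0.02, 2.0),
                ("MS", "mg"): self._fit(0.03, 2.0),
                ("ALS", "mg"): self._fit(0.04, 2.0)}
        out = sd.enrichment_heatmap_table(fits)
        assert len(out) == 4
        # BH across the 4 grid cells: all adjusted to 0.04
        assert out["q"].max() == pytest.approx(0.04)
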