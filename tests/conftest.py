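import numpy as np
import pytest

from chromrisk import simulate as sm
from chromrisk import loops as lm
from chromrisk.loops import TSS_WINDOW, _min_tss_distance


@pytest.fixture(scope="session")
def sim_cfg():
    return sm.SimConfig(seed=11, n_genes=20, n_snps=600, n_samples=400)


@pytest.fixture(scope="session")
def genome(sim_cfg):
    genes, peaks, loops = sm.simulate_genome(sim_cfg)
    return genes, peaks, loops


@pytest.fixture(scope="session")
def labels(genome):
    genes, peaks, loops = genome
    return lm.label_anchors(
        loops, peaks["h3k4me3"], peaks["h3k27ac"], peaks["atac"], genes
    )


@pytest.fixture(scope="session")
def panel(sim_cfg):
    return sm.simulate_ld_panel(sim_cfg)


@pytest.fixture(scope="session")
def enhancer_regions(genome):
    """Distal H3K27ac peaks of the toy genome."""
    genes, peaks, _ = genome
    tss = genes.tss_sites()
    return [p for p in peaks["h3k27ac"] if _min_tss_distance(p, tss) > TSS_WINDOW]


def brute_force_positional(ss, promoters, genes):
    """O(SNP x feature) containment scan, independent of the tree index."""
    feats = [(p.gene_id, p.interval) for p in promoters]
    feats += genes.exon_intervals()
    out = {}
    for snp, chrom, bp in zip(ss.table["snp"], ss.table["chrom"], ss.table["bp"]):
        for gid, iv in feats:
            if iv.contains(chrom, int(bp)):
                out.setdefault(gid, set()).add(snp)
    return out


def brute_force_interactional(ss, loops, enhancers, promoters, genes,
                              fdr_max=0.01):
    """Exhaustive (SNP, loop, gene) triple enumeration."""
    feats = [(p.gene_id, p.interval) for p in promoters]
    feats += genes.exon_intervals()
    prom_ivs = [p.interval for p in promoters]

    def positional_anywhere(chrom, bp):
        return any(iv.contains(chrom, bp) for _, iv in feats)

    kept = [
        lp for lp in loops
        if lp.fdr < fdr_max
        and any(a.overlaps(p) for p in prom_ivs for a in (lp.anchor_a, lp.anchor_b))
    ]
    out = {}
    for snp, chrom, bp in zip(ss.table["snp"], ss.table["chrom"], ss.table["bp"]):
        bp = int(bp)
        if positional_anywhere(chrom, bp):
            continue
        for lp in kept:
            for near, far in ((lp.anchor_a, lp.anchor_b),
                              (lp.anchor_b, lp.anchor_a)):
                if not near.contains(chrom, bp):
                    continue
                if not any(near.overlaps(e) for e in enhancers):
                    continue
                for gid, iv in feats:
                    if far.overlaps(iv):
                        out.setdefault(gid, set()).add(snp)
    return out
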