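"""Synthetic toy genomes, LD panels, GWAS summary statistics and expression.

Every generator is a pure function of :class:`SimConfig` (the root seed
included); per-stage random streams are derived deterministically from the
root seed so stages can be re-run independently.

The generated data emulate the structure of the real study inputs: 5 kb loop
anchor bins with promoter/enhancer architecture, LD-blocked genotype dosages,
GWAS Z-scores whose heritability is concentrated in chosen annotations, and a
cell-type expression matrix with marker-gene blocks. They do not emulate
realistic allele-frequency spectra, genetic maps or population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    GeneModel,
    GenomicInterval,
    LoopSet,
    SummaryStats,
    Transcript,
)

# stage identifiers mixed into the root seed for independent streams
_STAGE_GENOME = 1
_STAGE_PANEL = 2
_STAGE_GWAS = 3
_STAGE_EXPR = 4


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults give a small genome that exercises every downstream stage:
    two chromosomes of 2 Mb at 5 kb resolution, 40 genes, a 2,000-SNP /
    1,000-sample LD panel with AR(1) blocks, a 50,000-sample GWAS with
    total heritability 0.4, and a 4-cell-type expression reference.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 2_000_000
    bin_size: int = 5000
    n_genes: int = 40
    n_snps: int = 2000
    ld_block_size: int = 10
    ld_rho: float = 0.7
    n_samples: int = 1000
    gwas_n: float = 50_000.0
    h2_total: float = 0.4
    enrichment_spec: dict = field(default_factory=dict)
    n_cell_types: int = 4
    n_marker_genes: int = 8
    marker_fold: float = 10.0
    promoter_peak_fraction: float = 1.0
    loop_sig_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.chrom_length % self.bin_size:
            raise ValueError("bin_size must divide chrom_length")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.enrichment_spec and sum(self.enrichment_spec.values()) > 1 + 1e-9:
            raise ValueError("enrichment_spec shares must sum to <= 1")
        if not 0.0 <= self.promoter_peak_fraction <= 1.0:
            raise ValueError("promoter_peak_fraction must lie in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class TruthRecord:
    """Generative ground truth persisted alongside every simulated dataset."""

    seed: int
    effect_var: np.ndarray | None = None
    enrichment: dict = field(default_factory=dict)
    causal_genes: list = field(default_factory=list)


@dataclass
class Panel:
    """Reference genotype panel: dosage matrix plus SNP coordinates."""

    genotypes: np.ndarray  # n_samples x n_snps, centered-scale dosages
    snps: pd.DataFrame  # snp, chrom, bp, maf, block

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def correlation(self, idx=None) -> np.ndarray:
        """Empirical SNP correlation matrix (for the given column indices)."""
        g = self.genotypes if idx is None else self.genotypes[:, idx]
        g = g - g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        g = g / sd
        return (g.T @ g) / g.shape[0]


# ---------------------------------------------------------------------------
# Genome: genes, peaks, loops
# ---------------------------------------------------------------------------

# per-unit bin roles; each repeating unit of 12 bins realizes every loop
# category: P promoter, PE promoter+distal-enhancer, E enhancer, K distal
# H3K4me3, A ATAC-only, O other (no peaks)
_UNIT_BINS = 12
_ROLE = {0: "P", 2: "E", 3: "E", 4: "E", 5: "PE", 6: "K", 7: "A", 8: "O",
         9: "K", 10: "E"}
# loops wired within a unit (bin offset pairs); promoter-to-enhancer pairs
# form the majority, and the eight categories are all covered
_UNIT_LOOPS = [
    (0, 2), (0, 3), (0, 4), (0, 10),   # promoter -> enhancer
    (5, 2), (5, 3), (5, 4), (5, 10),   # promoter/enhancer -> enhancer
    (0, 5),   # promoter -> promoter/enhancer
    (0, 7),   # promoter -> ATAC
    (0, 8),   # promoter -> other
    (6, 9),   # H3K4me3 -> H3K4me3
    (6, 8),   # H3K4me3 -> other
    (4, 10),  # enhancer -> enhancer => "other" category
]
# plus one promoter -> promoter loop between consecutive units per chromosome


def simulate_genome(cfg: SimConfig):
    """Build a toy genome: gene model, peak sets and a loop set.

    Returns ``(GeneModel, peaks, LoopSet)`` where ``peaks`` is a dict with
    keys ``h3k4me3``, ``h3k27ac``, ``atac`` mapping to interval lists.
    Promoter bins carry H3K4me3+H3K27ac peaks near the TSS, enhancer bins
    carry distal H3K27ac-only peaks, and loops wire all eight interaction
    categories with a configurable fraction passing the FDR 0.01 filter.
    """
    rng = cfg.rng(_STAGE_GENOME)
    bins_per_chrom = cfg.chrom_length // cfg.bin_size
    units_per_chrom = bins_per_chrom // _UNIT_BINS
    total_units = cfg.n_chrom * units_per_chrom
    # two genes per unit (bins P and PE)
    if cfg.n_genes > 2 * total_units:
        raise ValueError(
            f"cannot place {cfg.n_genes} genes: genome holds "
            f"{2 * total_units} gene slots at this geometry"
        )
    if total_units < 1:
        raise ValueError("chromosomes too short for one 12-bin unit")

    transcripts: list[Transcript] = []
    h3k4me3: list[GenomicInterval] = []
    h3k27ac: list[GenomicInterval] = []
    atac: list[GenomicInterval] = []
    pairs = []

    def bin_iv(chrom: str, b: int) -> GenomicInterval:
        return GenomicInterval(chrom, b * cfg.bin_size, (b + 1) * cfg.bin_size)

    # units interleave round-robin across chromosomes so populated units
    # (and thus annotations) cover every chromosome; only units holding
    # genes are given peaks and loops
    n_units_used = (cfg.n_genes + 1) // 2
    gene_slots = []  # (chrom, bin_index, role)
    unit_starts = []  # (chrom, first bin of unit)
    for u in range(units_per_chrom):
        for c in range(cfg.n_chrom):
            if len(unit_starts) >= n_units_used:
                break
            chrom = f"chr{c + 1}"
            b0 = u * _UNIT_BINS
            unit_starts.append((chrom, b0))
            gene_slots.append((chrom, b0 + 0, "P"))
            gene_slots.append((chrom, b0 + 5, "PE"))

    gene_idx = 0
    for chrom, b, role in gene_slots:
        if gene_idx >= cfg.n_genes:
            break
        gene_id = f"G{gene_idx + 1:04d}"
        start = b * cfg.bin_size
        strand = "+" if gene_idx % 2 == 0 else "-"
        # TSS near the left edge of the bin so promoter peaks fit inside it
        # and stay > 2 kb clear of the in-bin distal enhancer peak; on '-'
        # the TSS sits further right so leftward exons stay on-chromosome
        tss0 = start + (500 if strand == "+" else 1200)
        n_tx = int(rng.integers(1, 4))
        for t in range(n_tx):
            tss = tss0 + int(rng.integers(0, 100)) if t else tss0
            if strand == "+":
                exons = (
                    GenomicInterval(chrom, tss, tss + 300, strand),
                    GenomicInterval(chrom, tss + 800, tss + 1100, strand),
                )
            else:
                # TSS is the rightmost transcribed base; exons extend left
                exons = (
                    GenomicInterval(chrom, tss - 300, tss, strand),
                    GenomicInterval(chrom, tss - 1100, tss - 800, strand),
                )
            transcripts.append(
                Transcript(gene_id, f"{gene_id}.T{t + 1}", chrom, strand, tss, exons)
            )
        # promoter peaks around the TSS (fraction of genes may lack them)
        if rng.random() < cfg.promoter_peak_fraction:
            h3k4me3.append(GenomicInterval(chrom, start + 200, start + 1000))
            h3k27ac.append(GenomicInterval(chrom, start + 200, start + 1000))
        if role == "PE":
            # distal H3K27ac in the same bin, > 2 kb from every TSS
            h3k27ac.append(GenomicInterval(chrom, start + 3500, start + 3900))
        gene_idx += 1

    for chrom, b0 in unit_starts:
        for off, role in _ROLE.items():
            iv = bin_iv(chrom, b0 + off)
            if role == "E":
                h3k27ac.append(
                    GenomicInterval(chrom, iv.start + 2000, iv.start + 2400)
                )
            elif role == "K":
                h3k4me3.append(
                    GenomicInterval(chrom, iv.start + 2000, iv.start + 2400)
                )
            elif role == "A":
                atac.append(GenomicInterval(chrom, iv.start + 2000, iv.start + 2400))

    def draw_fdr() -> float:
        if rng.random() < cfg.loop_sig_fraction:
            return float(rng.uniform(1e-6, 0.009))
        return float(rng.uniform(0.011, 0.5))

    last_p_bin: dict[str, int] = {}
    for chrom, b0 in unit_starts:
        for oa, ob in _UNIT_LOOPS:
            pairs.append((bin_iv(chrom, b0 + oa), bin_iv(chrom, b0 + ob), draw_fdr()))
        # promoter -> promoter loop to the previous unit on this chromosome
        if chrom in last_p_bin:
            pairs.append(
                (bin_iv(chrom, last_p_bin[chrom]), bin_iv(chrom, b0), draw_fdr())
            )
        last_p_bin[chrom] = b0

    genes = GeneModel(transcripts)
    peaks = {
        "h3k4me3": sorted(h3k4me3, key=lambda p: (p.chrom, p.start)),
        "h3k27ac": sorted(h3k27ac, key=lambda p: (p.chrom, p.start)),
        "atac": sorted(atac, key=lambda p: (p.chrom, p.start)),
    }
    loops = LoopSet.from_pairs(pairs, resolution=cfg.bin_size, cell_type="sim")
    return genes, peaks, loops


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------


def simulate_ld_panel(cfg: SimConfig) -> Panel:
    """Simulate a reference panel of Gaussian genotype dosages.

    SNPs are laid out evenly across the toy genome and grouped into LD
    blocks of ``ld_block_size`` consecutive SNPs (blocks never span
    chromosomes). Within a block, dosages follow an AR(1) correlation
    ``ld_rho ** |i - j|``; blocks are independent. Dosage means encode an
    allele frequency drawn uniformly in [0.1, 0.45] so empirical MAF stays
    inside [0.05, 0.5].
    """
    rng = cfg.rng(_STAGE_PANEL)
    per_chrom = [cfg.n_snps // cfg.n_chrom] * cfg.n_chrom
    per_chrom[-1] += cfg.n_snps - sum(per_chrom)

    rows = []
    block = -1
    for c, n_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        # even grid with jitter, clear of chromosome edges
        step = cfg.chrom_length / (n_c + 1)
        pos = np.sort(
            (np.arange(1, n_c + 1) * step
             + rng.uniform(-0.3 * step, 0.3 * step, n_c)).astype(int)
        )
        pos = np.clip(pos, 1, cfg.chrom_length - 2)
        for i, bp in enumerate(pos):
            if i % cfg.ld_block_size == 0:
                block += 1
            rows.append((chrom, int(bp), block))
    snps = pd.DataFrame(rows, columns=["chrom", "bp", "block"])
    snps.insert(0, "snp", [f"rs{i + 1}" for i in range(len(snps))])
    freq = rng.uniform(0.10, 0.45, len(snps))
    snps["maf"] = freq

    # AR(1) latent gaussians per block, then affine map to dosage scale
    x = np.empty((cfg.n_samples, len(snps)))
    for _, idx in snps.groupby("block").groups.items():
        idx = np.asarray(idx)
        e = rng.standard_normal((cfg.n_samples, len(idx)))
        z = np.empty_like(e)
        z[:, 0] = e[:, 0]
        for j in range(1, len(idx)):
            z[:, j] = cfg.ld_rho * z[:, j - 1] + np.sqrt(1 - cfg.ld_rho**2) * e[:, j]
        x[:, idx] = z
    dosage = 2 * freq + np.sqrt(2 * freq * (1 - freq)) * x
    emp = dosage.mean(axis=0) / 2
    snps["maf"] = np.minimum(emp, 1 - emp)
    return Panel(genotypes=dosage, snps=snps)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def simulate_gwas(
    panel: Panel, annotations: dict[str, np.ndarray], cfg: SimConfig
) -> tuple[SummaryStats, TruthRecord]:
    """Simulate marginal GWAS Z-scores with annotation-partitioned h².

    Each annotation named in ``cfg.enrichment_spec`` receives its share of
    ``h2_total``, spread equally over its member SNPs; the remaining share
    is spread over SNPs outside every named annotation. Marginal scores are
    ``Z = sqrt(N) R beta + L eps`` computed blockwise with the panel's
    *empirical* LD, so downstream LD-aware methods see consistent LD.
    """
    if cfg.h2_total < 0:
        raise ValueError("h2_total must be >= 0")
    if cfg.h2_total <= 0 and cfg.enrichment_spec:
        raise ValueError("h2_total must be > 0 when enrichment_spec is nonempty")
    m = panel.n_snps
    for name, mask in annotations.items():
        if len(mask) != m:
            raise ValueError(f"annotation {name!r} length != panel SNP count")

    rng = cfg.rng(_STAGE_GWAS)
    sigma2 = np.zeros(m)
    covered = np.zeros(m, dtype=bool)
    for name, share in cfg.enrichment_spec.items():
        mask = np.asarray(annotations[name], dtype=bool)
        if mask.sum() == 0:
            raise ValueError(f"annotation {name!r} is empty")
        sigma2[mask] += share * cfg.h2_total / mask.sum()
        covered |= mask
    rest = 1.0 - sum(cfg.enrichment_spec.values()) if cfg.enrichment_spec else 1.0
    outside = ~covered
    if outside.any() and cfg.h2_total > 0:
        sigma2[outside] += rest * cfg.h2_total / outside.sum()

    beta = rng.standard_normal(m) * np.sqrt(sigma2)
    z = np.empty(m)
    eps = rng.standard_normal(m)
    for _, idx in panel.snps.groupby("block").groups.items():
        idx = np.asarray(idx)
        r = panel.correlation(idx)
        try:
            chol = np.linalg.cholesky(r + 1e-10 * np.eye(len(idx)))
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(r + 1e-6 * np.eye(len(idx)))
        z[idx] = np.sqrt(cfg.gwas_n) * (r @ beta[idx]) + chol @ eps[idx]

    p = np.clip(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    table = pd.DataFrame({
        "snp": panel.snps["snp"],
        "chrom": panel.snps["chrom"],
        "bp": panel.snps["bp"],
        "a1": "A",
        "a2": "G",
        "z": z,
        "p": p,
        "n": cfg.gwas_n,
        "info": 1.0,
        "maf": panel.snps["maf"],
    })
    truth_enr = {}
    for name, mask in annotations.items():
        mask = np.asarray(mask, dtype=bool)
        prop_snps = mask.sum() / m
        prop_h2 = sigma2[mask].sum() / sigma2.sum() if sigma2.sum() > 0 else 0.0
        truth_enr[name] = prop_h2 / prop_snps if prop_snps > 0 else np.nan
    truth = TruthRecord(seed=cfg.seed, effect_var=sigma2, enrichment=truth_enr)
    return SummaryStats(table), truth


# ---------------------------------------------------------------------------
# Expression reference
# ---------------------------------------------------------------------------


def simulate_expression(cfg: SimConfig) -> pd.DataFrame:
    """Gene x cell-type mean-expression matrix with marker-gene blocks.

    Cell type ``c`` gets ``n_marker_genes`` markers whose expression is
    elevated ``marker_fold``-fold over their flat baseline; all other genes
    are expressed uniformly across cell types (gene-specific baseline).
    """
    if cfg.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if cfg.n_marker_genes * cfg.n_cell_types > cfg.n_genes:
        raise ValueError("marker sets exceed gene count")
    rng = cfg.rng(_STAGE_EXPR)
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    cell_types = [f"CT{c + 1}" for c in range(cfg.n_cell_types)]
    base = rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_genes)
    expr = np.tile(base[:, None], (1, cfg.n_cell_types))
    for c in range(cfg.n_cell_types):
        lo = c * cfg.n_marker_genes
        expr[lo:lo + cfg.n_marker_genes, c] *= cfg.marker_fold
    return pd.DataFrame(expr, index=genes, columns=cell_types)


def marker_genes(cfg: SimConfig, cell_type: str) -> list[str]:
    """The marker-gene list planted for one cell type by simulate_expression."""
    c = int(cell_type.removeprefix("CT")) - 1
    lo = c * cfg.n_marker_genes
    return [f"G{i + 1:04d}" for i in range(lo, lo + cfg.n_marker_genes)]
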