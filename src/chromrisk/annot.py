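"""Interaction-based SNP-to-gene annotation (the H-MAGMA input builder).

Exonic and promoter SNPs are assigned to their host genes by position;
intronic and intergenic SNPs are routed to genes through significant,
promoter-anchored chromatin loops when they fall inside an enhancer-
overlapping anchor bin whose partner anchor touches the gene's promoter or
exons. Promoters span 1.5 kb upstream to 500 bp downstream of each isoform
TSS. Subset annotations (positional-only, enhancer-only) and a plain 10 kb
proximity window are built through the same interface, plus the seeded
loop-downsampling used to equalize loop numbers across cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from intervaltree import IntervalTree

from .genome_io import GeneModel, GeneSnpMap, GenomicInterval, LoopSet, SummaryStats

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
DEFAULT_FDR_MAX = 0.01
WINDOW_10KB = 10_000


class AnnotMode(str, Enum):
    FULL = "full"
    POSITIONAL_ONLY = "positional_only"
    ENHANCER_ONLY = "enhancer_only"
    WINDOW10KB = "window10kb"


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    transcript_id: str
    interval: GenomicInterval


def build_promoters(genes: GeneModel) -> list[Promoter]:
    """One promoter interval per transcript, strand-aware, clipped at 0.

    '+' strand: [tss - 1500, tss + 500); '-' strand: [tss - 500, tss + 1500),
    i.e. the upstream side lies to the right of the TSS.
    """
    out = []
    for t in genes.transcripts:
        if t.strand == "+":
            start, end = t.tss - PROMOTER_UPSTREAM, t.tss + PROMOTER_DOWNSTREAM
        else:
            start, end = t.tss - PROMOTER_DOWNSTREAM, t.tss + PROMOTER_UPSTREAM
        start = max(start, 0)
        out.append(
            Promoter(t.gene_id, t.transcript_id,
                     GenomicInterval(t.chrom, start, end, t.strand))
        )
    return out


class _FeatureIndex:
    """Per-chromosome interval index of (gene_id, interval) features."""

    def __init__(self, features):
        self.trees: dict[str, IntervalTree] = {}
        for gene_id, iv in features:
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, gene_id
            )

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos)}

    def genes_overlapping(self, iv: GenomicInterval) -> set[str]:
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(iv.start, iv.end)}

    def any_at(self, chrom: str, pos: int) -> bool:
        tree = self.trees.get(chrom)
        return tree is not None and bool(tree.at(pos))

    def any_overlapping(self, iv: GenomicInterval) -> bool:
        tree = self.trees.get(iv.chrom)
        return tree is not None and tree.overlaps(iv.start, iv.end)


def _positional_features(promoters, genes: GeneModel):
    feats = [(p.gene_id, p.interval) for p in promoters]
    feats.extend(genes.exon_intervals())
    return feats


def filter_loops(
    loops: LoopSet, promoters, fdr_max: float = DEFAULT_FDR_MAX
) -> LoopSet:
    """Significant, promoter-anchored loops: fdr < fdr_max and at least one
    anchor overlapping a promoter interval."""
    prom_idx = _FeatureIndex((p.gene_id, p.interval) for p in promoters)
    kept = [
        lp
        for lp in loops
        if lp.fdr < fdr_max
        and (prom_idx.any_overlapping(lp.anchor_a)
             or prom_idx.any_overlapping(lp.anchor_b))
    ]
    out = LoopSet(loops=kept, resolution=loops.resolution, cell_type=loops.cell_type)
    logger.info("filter_loops: %d of %d retained", len(kept), len(loops))
    return out


def _set_spans(gmap: GeneSnpMap, genes: GeneModel, feature_index: _FeatureIndex | None,
               promoters=None) -> None:
    """Gene span = min/max over the gene's positional features, else gene body."""
    feat_by_gene: dict[str, list[GenomicInterval]] = {}
    if promoters is not None:
        for p in promoters:
            feat_by_gene.setdefault(p.gene_id, []).append(p.interval)
    for gid, iv in genes.exon_intervals():
        feat_by_gene.setdefault(gid, []).append(iv)
    for gid in gmap.snps:
        ivs = feat_by_gene.get(gid)
        if ivs:
            gmap.spans[gid] = (
                ivs[0].chrom,
                min(i.start for i in ivs),
                max(i.end for i in ivs),
            )
        else:
            body = genes.gene_body(gid)
            gmap.spans[gid] = (body.chrom, body.start, body.end)


def assign_positional(
    snps: SummaryStats, promoters, genes: GeneModel
) -> GeneSnpMap:
    """Assign each SNP lying inside a promoter or exon directly to the gene.

    A SNP may map to multiple genes (isoform overlap is allowed).
    """
    idx = _FeatureIndex(_positional_features(promoters, genes))
    gmap = GeneSnpMap()
    tbl = snps.table
    for snp, chrom, bp in zip(tbl["snp"], tbl["chrom"], tbl["bp"]):
        for gid in sorted(idx.genes_at(chrom, int(bp))):
            gmap.add(gid, snp)
    _set_spans(gmap, genes, idx, promoters)
    return gmap


def assign_interactional(
    snps: SummaryStats,
    filtered_loops: LoopSet,
    enhancers,
    promoters,
    genes: GeneModel,
) -> GeneSnpMap:
    """Route intronic/intergenic enhancer SNPs to genes through loops.

    A SNP gains gene ``g`` iff (i) the SNP is intronic or intergenic — it
    lies in no promoter or exon interval of any gene; (ii) it lies inside a
    loop anchor bin that overlaps an enhancer region; and (iii) the partner
    anchor overlaps a promoter or exon of ``g``. ``filtered_loops`` must
    already be significant and promoter-anchored.
    """
    pos_idx = _FeatureIndex(_positional_features(promoters, genes))
    enh_idx = _FeatureIndex(("", e) for e in enhancers)
    gmap = GeneSnpMap()
    tbl = snps.table

    # anchor -> (overlaps enhancer?, genes whose promoter/exon it touches)
    anchor_info: dict[tuple, tuple[bool, set]] = {}

    def info(iv: GenomicInterval):
        key = (iv.chrom, iv.start, iv.end)
        if key not in anchor_info:
            anchor_info[key] = (
                enh_idx.any_overlapping(iv),
                pos_idx.genes_overlapping(iv),
            )
        return anchor_info[key]

    # SNPs per anchor bin
    snp_rows = list(zip(tbl["snp"], tbl["chrom"], tbl["bp"]))
    eligible = [
        (s, c, int(b)) for s, c, b in snp_rows if not pos_idx.any_at(c, int(b))
    ]
    for lp in filtered_loops:
        for snp_side, gene_side in ((lp.anchor_a, lp.anchor_b),
                                    (lp.anchor_b, lp.anchor_a)):
            side_enh, _ = info(snp_side)
            if not side_enh:
                continue
            _, target_genes = info(gene_side)
            if not target_genes:
                continue
            for snp, chrom, bp in eligible:
                if snp_side.contains(chrom, bp):
                    for gid in sorted(target_genes):
                        gmap.add(gid, snp)
    _set_spans(gmap, genes, pos_idx, promoters)
    return gmap


def assign_window(
    snps: SummaryStats, genes: GeneModel, window: int = WINDOW_10KB
) -> GeneSnpMap:
    """Proximity annotation: every SNP within ``window`` bp of a gene body."""
    feats = []
    for gid in genes.gene_ids:
        body = genes.gene_body(gid)
        feats.append(
            (gid, GenomicInterval(body.chrom, max(0, body.start - window),
                                  body.end + window))
        )
    idx = _FeatureIndex(feats)
    gmap = GeneSnpMap()
    tbl = snps.table
    for snp, chrom, bp in zip(tbl["snp"], tbl["chrom"], tbl["bp"]):
        for gid in sorted(idx.genes_at(chrom, int(bp))):
            gmap.add(gid, snp)
    _set_spans(gmap, genes, None, None)
    return gmap


def build_annotation(
    mode: AnnotMode | str,
    snps: SummaryStats,
    genes: GeneModel,
    loops: LoopSet | None = None,
    enhancers=None,
    fdr_max: float = DEFAULT_FDR_MAX,
    restrict_positional_to_bins: bool = True,
) -> GeneSnpMap:
    """Build the gene->SNP annotation for one mode.

    full: positional union interactional. positional_only: positional
    assignments restricted to SNPs inside promoter/exon-overlapping anchor
    bins of the filtered loops (set ``restrict_positional_to_bins=False``
    for genome-wide positional assignment). enhancer_only: interactional
    assignments alone. window10kb: plain 10 kb gene-body proximity.
    """
    mode = AnnotMode(mode)
    promoters = build_promoters(genes)
    if mode is AnnotMode.WINDOW10KB:
        return assign_window(snps, genes)
    needs_loops = mode in (AnnotMode.FULL, AnnotMode.ENHANCER_ONLY) or (
        mode is AnnotMode.POSITIONAL_ONLY and restrict_positional_to_bins
    )
    if needs_loops and loops is None:
        raise ValueError(f"mode {mode.value} requires loops")
    if mode in (AnnotMode.FULL, AnnotMode.ENHANCER_ONLY) and enhancers is None:
        raise ValueError(f"mode {mode.value} requires enhancer regions")
    flt = filter_loops(loops, promoters, fdr_max) if loops is not None else None

    if mode is AnnotMode.ENHANCER_ONLY:
        return assign_interactional(snps, flt, enhancers, promoters, genes)
    positional = assign_positional(snps, promoters, genes)
    if mode is AnnotMode.POSITIONAL_ONLY:
        if not restrict_positional_to_bins:
            return positional
        pos_idx = _FeatureIndex(_positional_features(promoters, genes))
        bins = [
            iv for iv in flt.anchors() if pos_idx.any_overlapping(iv)
        ]
        bin_idx = _FeatureIndex(("", iv) for iv in bins)
        bp_of = dict(zip(snps.table["snp"], zip(snps.table["chrom"], snps.table["bp"])))
        out = GeneSnpMap()
        for gid, ids in positional.snps.items():
            for s in ids:
                chrom, bp = bp_of[s]
                if bin_idx.any_at(chrom, int(bp)):
                    out.add(gid, s)
        for gid in out.snps:
            out.spans[gid] = positional.spans[gid]
        return out
    # full
    interactional = assign_interactional(snps, flt, enhancers, promoters, genes)
    return positional.union(interactional)


def downsample_loops(loops: LoopSet, n: int, seed: int) -> LoopSet:
    """Uniform sample of ``n`` loops without replacement, seeded."""
    if n > len(loops):
        raise ValueError(f"cannot sample {n} from {len(loops)} loops")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(loops), size=n, replace=False))
    return LoopSet(
        loops=[loops.loops[i] for i in idx],
        resolution=loops.resolution,
        cell_type=loops.cell_type,
    )
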