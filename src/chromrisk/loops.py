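"""Classify loop anchor bins and interactions against epigenomic peaks.

Anchor bins are labeled by their overlap with H3K4me3 / H3K27ac / ATAC peaks
and their distance to transcription start sites, then each loop falls into
one of eight interaction categories (promoter-to-enhancer, promoter-to-
promoter, ... , other). Categories partition the loop set: the per-category
counts always sum to the total.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum

import numpy as np

from .genome_io import GeneModel, GenomicInterval, LoopSet

TSS_WINDOW = 2000  # bp: a promoter bin lies within this distance of a TSS


class BinLabel(str, Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"
    PROMOTER_ENHANCER = "promoter_enhancer"
    H3K4ME3_DISTAL = "h3k4me3_distal"
    ATAC_ONLY = "atac_only"
    OTHER = "other"


class LoopCategory(str, Enum):
    PROMOTER_TO_ENHANCER = "promoter_to_enhancer"
    PROMOTER_TO_PROMOTER = "promoter_to_promoter"
    PROMOTER_TO_ATAC = "promoter_to_atac"
    PROMOTER_TO_PROMOTER_ENHANCER = "promoter_to_promoter_enhancer"
    PROMOTER_TO_OTHER = "promoter_to_other"
    H3K4ME3_TO_H3K4ME3 = "h3k4me3_to_h3k4me3"
    H3K4ME3_TO_OTHER = "h3k4me3_to_other"
    OTHER = "other"


def _interval_to_point(iv: GenomicInterval, pos: int) -> int:
    """bp distance from a half-open interval to a position (0 if inside)."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


def _min_tss_distance(iv: GenomicInterval, tss_sites) -> float:
    dists = [
        _interval_to_point(iv, pos) for chrom, pos in tss_sites if chrom == iv.chrom
    ]
    return min(dists) if dists else np.inf


def _overlaps_any(iv: GenomicInterval, peaks) -> bool:
    return any(iv.overlaps(p) for p in peaks)


def label_bin(
    bin_iv: GenomicInterval,
    h3k4me3,
    h3k27ac,
    atac,
    tss_sites,
    tss_window: int = TSS_WINDOW,
) -> BinLabel:
    """Assign the single functional label of one anchor bin.

    Promoter: overlaps both an H3K4me3 and an H3K27ac peak and lies within
    ``tss_window`` bp of a TSS. Enhancer: overlaps an H3K27ac peak that is
    itself distal (> ``tss_window``) to every TSS. A bin qualifying for
    both is promoter_enhancer. H3K4me3_distal: overlaps H3K4me3 without a
    promoter call. ATAC_only: overlaps an ATAC peak and is devoid of
    H3K4me3 and H3K27ac. Residual: other. Precedence:
    promoter_enhancer > promoter > enhancer > h3k4me3_distal > atac_only.
    """
    has_k4 = _overlaps_any(bin_iv, h3k4me3)
    has_k27 = _overlaps_any(bin_iv, h3k27ac)
    near_tss = _min_tss_distance(bin_iv, tss_sites) <= tss_window
    promoter_call = has_k4 and has_k27 and near_tss
    distal_k27 = any(
        bin_iv.overlaps(p) and _min_tss_distance(p, tss_sites) > tss_window
        for p in h3k27ac
    )
    if promoter_call and distal_k27:
        return BinLabel.PROMOTER_ENHANCER
    if promoter_call:
        return BinLabel.PROMOTER
    if distal_k27:
        return BinLabel.ENHANCER
    if has_k4:
        return BinLabel.H3K4ME3_DISTAL
    if not has_k27 and _overlaps_any(bin_iv, atac):
        return BinLabel.ATAC_ONLY
    return BinLabel.OTHER


def label_anchors(
    loops: LoopSet, h3k4me3, h3k27ac, atac, genes: GeneModel
) -> dict[tuple, BinLabel]:
    """Label every distinct anchor bin of a loop set, keyed by coordinates."""
    tss_sites = genes.tss_sites()
    return {
        (iv.chrom, iv.start, iv.end): label_bin(iv, h3k4me3, h3k27ac, atac, tss_sites)
        for iv in loops.anchors()
    }


_PROMOTER_SIDE = {BinLabel.PROMOTER, BinLabel.PROMOTER_ENHANCER}
_PARTNER_CLASS = {
    BinLabel.ENHANCER: LoopCategory.PROMOTER_TO_ENHANCER,
    BinLabel.PROMOTER: LoopCategory.PROMOTER_TO_PROMOTER,
    BinLabel.ATAC_ONLY: LoopCategory.PROMOTER_TO_ATAC,
    BinLabel.PROMOTER_ENHANCER: LoopCategory.PROMOTER_TO_PROMOTER_ENHANCER,
    BinLabel.H3K4ME3_DISTAL: LoopCategory.PROMOTER_TO_OTHER,
    BinLabel.OTHER: LoopCategory.PROMOTER_TO_OTHER,
}


def classify_loop(label_a: BinLabel, label_b: BinLabel) -> LoopCategory:
    """Map an unordered pair of anchor labels to its interaction category."""
    a_prom, b_prom = label_a in _PROMOTER_SIDE, label_b in _PROMOTER_SIDE
    if a_prom or b_prom:
        if a_prom and b_prom:
            if BinLabel.PROMOTER_ENHANCER in (label_a, label_b):
                return LoopCategory.PROMOTER_TO_PROMOTER_ENHANCER
            return LoopCategory.PROMOTER_TO_PROMOTER
        partner = label_b if a_prom else label_a
        return _PARTNER_CLASS[partner]
    if BinLabel.H3K4ME3_DISTAL in (label_a, label_b):
        if label_a == label_b == BinLabel.H3K4ME3_DISTAL:
            return LoopCategory.H3K4ME3_TO_H3K4ME3
        return LoopCategory.H3K4ME3_TO_OTHER
    return LoopCategory.OTHER


def _loop_label(labels, iv: GenomicInterval) -> BinLabel:
    key = (iv.chrom, iv.start, iv.end)
    if key not in labels:
        raise KeyError(f"unlabeled anchor {iv.chrom}:{iv.start}-{iv.end}")
    return labels[key]


def loop_categories(loops: LoopSet, labels) -> list[LoopCategory]:
    return [
        classify_loop(_loop_label(labels, lp.anchor_a), _loop_label(labels, lp.anchor_b))
        for lp in loops
    ]


def category_counts(loops: LoopSet, labels) -> dict:
    """Counts and fractions per category; counts sum to the loop total."""
    if len(loops) == 0:
        raise ValueError("empty LoopSet")
    cats = loop_categories(loops, labels)
    counts = Counter(cats)
    total = len(loops)
    return {
        "total": total,
        "counts": {c.value: counts.get(c, 0) for c in LoopCategory},
        "fractions": {c.value: counts.get(c, 0) / total for c in LoopCategory},
    }


def degree_distributions(loops: LoopSet, labels):
    """Partner-count histograms over promoter-to-enhancer loops.

    Returns (enhancers-per-promoter, promoters-per-enhancer) as
    ``Counter({degree: n_bins})``; degrees count distinct partner bins.
    """
    prom_partners: dict[tuple, set] = {}
    enh_partners: dict[tuple, set] = {}
    for lp in loops:
        la = _loop_label(labels, lp.anchor_a)
        lb = _loop_label(labels, lp.anchor_b)
        if classify_loop(la, lb) != LoopCategory.PROMOTER_TO_ENHANCER:
            continue
        if la in _PROMOTER_SIDE:
            prom, enh = lp.anchor_a, lp.anchor_b
        else:
            prom, enh = lp.anchor_b, lp.anchor_a
        pk = (prom.chrom, prom.start, prom.end)
        ek = (enh.chrom, enh.start, enh.end)
        prom_partners.setdefault(pk, set()).add(ek)
        enh_partners.setdefault(ek, set()).add(pk)
    enh_per_prom = Counter(len(v) for v in prom_partners.values())
    prom_per_enh = Counter(len(v) for v in enh_partners.values())
    return enh_per_prom, prom_per_enh


def distance_stats(loops: LoopSet, labels) -> dict:
    """Midpoint distances of promoter-to-enhancer loops (cis only).

    Trans-chromosomal pairs are excluded from the distances and counted.
    """
    distances = []
    n_trans = 0
    for lp, cat in zip(loops, loop_categories(loops, labels)):
        if cat != LoopCategory.PROMOTER_TO_ENHANCER:
            continue
        if lp.anchor_a.chrom != lp.anchor_b.chrom:
            n_trans += 1
            continue
        distances.append(abs(lp.anchor_a.midpoint - lp.anchor_b.midpoint))
    summary = {
        "n": len(distances),
        "n_trans_excluded": n_trans,
        "mean": float(np.mean(distances)) if distances else np.nan,
        "min": float(np.min(distances)) if distances else np.nan,
        "max": float(np.max(distances)) if distances else np.nan,
    }
    return {"distances": distances, "summary": summary}
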