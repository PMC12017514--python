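"""Stratified LD score regression: partitioned heritability by annotation.

Per-SNP chi-square statistics are regressed jointly on annotation-stratified
LD scores, E[chi2_j] = N sum_C tau_C l(j,C) + 1, by weighted least squares.
Each annotation's heritability share follows from its coefficients, and
enrichment is the share of heritability over the share of SNPs. Standard
errors come from a leave-one-block-out jackknife over contiguous SNP blocks.

The toy pipeline computes LD scores in a base-pair window (real analyses use
a genetic-map window) and uses a small configurable baseline instead of the
full 97-category baseline model; both divergences are documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import SummaryStats
from .loops import BinLabel, LoopSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_N_BLOCKS = 200

_PROM_LABELS = {BinLabel.PROMOTER, BinLabel.PROMOTER_ENHANCER}
_ENH_LABELS = {BinLabel.ENHANCER, BinLabel.PROMOTER_ENHANCER}


def category_bin_sets(loops: LoopSet, labels) -> dict[str, list]:
    """Anchor-bin sets for the four functional categories.

    total: every anchor bin; promoter: promoter-labeled anchors;
    enhancer: enhancer-labeled anchors; promoter_enhancer: the union of
    the promoter and enhancer anchor sets.
    """
    anchors = loops.anchors()

    def lab(iv):
        return labels[(iv.chrom, iv.start, iv.end)]

    prom = [iv for iv in anchors if lab(iv) in _PROM_LABELS]
    enh = [iv for iv in anchors if lab(iv) in _ENH_LABELS]
    prom_enh = sorted(
        {(iv.chrom, iv.start, iv.end): iv for iv in prom + enh}.values(),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    return {
        "total": anchors,
        "promoter_enhancer": list(prom_enh),
        "promoter": prom,
        "enhancer": enh,
    }


def bins_to_annotations(
    bin_sets: dict[str, list], snps: pd.DataFrame
) -> pd.DataFrame:
    """SNP x annotation binary membership matrix, with an all-ones base.

    A SNP belongs to an annotation iff its position lies inside any of the
    annotation's (half-open) bins. ``snps`` needs columns snp/chrom/bp.
    """
    out = pd.DataFrame({"base": np.ones(len(snps), dtype=int)},
                       index=pd.Index(snps["snp"], name="snp"))
    chrom = snps["chrom"].to_numpy()
    bp = snps["bp"].to_numpy()
    for name, bins in bin_sets.items():
        member = np.zeros(len(snps), dtype=bool)
        for iv in bins:
            member |= (chrom == iv.chrom) & (bp >= iv.start) & (bp < iv.end)
        out[name] = member.astype(int)
    return out


def compute_ld_scores(
    panel, annot: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """Stratified LD scores l(j, C) with bias-corrected r-squared.

    l(j,C) = sum over annotation-C SNPs k with |bp_k - bp_j| <= window of
    r2_adj(j,k), where r2_adj = r2 - (1 - r2)/(n - 2) corrects the upward
    finite-sample bias of the squared sample correlation.
    """
    n = panel.n_samples
    if n < 3:
        raise ValueError("need at least 3 panel samples")
    A = annot.loc[panel.snps["snp"]].to_numpy(float)
    scores = np.zeros((panel.n_snps, A.shape[1]))
    for chrom, idx in panel.snps.groupby("chrom").groups.items():
        idx = np.asarray(idx)
        r = panel.correlation(idx)
        r2 = r**2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        bp = panel.snps["bp"].to_numpy()[idx]
        in_window = np.abs(bp[:, None] - bp[None, :]) <= window_bp
        scores[idx] = (r2_adj * in_window) @ A[idx]
    return pd.DataFrame(scores, index=pd.Index(panel.snps["snp"], name="snp"),
                        columns=annot.columns)


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def munge_for_ldsc(
    ss: SummaryStats,
    info_min: float = 0.9,
    maf_min: float = 0.01,
    keep_snps=None,
) -> tuple[SummaryStats, dict]:
    """LDSC-style munging of summary statistics.

    Drops SNPs with INFO <= ``info_min`` or MAF <= ``maf_min``, strand-
    ambiguous alleles (A/T, C/G), duplicated IDs, and — when ``keep_snps``
    is given — anything outside that well-imputed SNP list (the stand-in
    for the HapMap3 restriction).
    """
    df = ss.table.copy()
    report = {"input": len(df)}
    bad = df["info"].fillna(1.0) <= info_min
    report["dropped_info"] = int(bad.sum())
    df = df[~bad]
    bad = df["maf"].fillna(0.5) <= maf_min
    report["dropped_maf"] = int(bad.sum())
    df = df[~bad]
    amb = [
        (str(a1).upper(), str(a2).upper()) in _AMBIGUOUS
        for a1, a2 in zip(df["a1"], df["a2"])
    ]
    report["dropped_ambiguous"] = int(np.sum(amb))
    df = df[~np.asarray(amb)]
    dup = df["snp"].duplicated(keep=False)
    report["dropped_duplicate_id"] = int(dup.sum())
    df = df[~dup]
    if keep_snps is not None:
        keep = set(keep_snps)
        bad = ~df["snp"].isin(keep)
        report["dropped_not_in_list"] = int(bad.sum())
        df = df[~bad]
    report["output"] = len(df)
    if len(df) == 0:
        raise ValueError("munging removed every SNP")
    return SummaryStats(df.reset_index(drop=True)), report


@dataclass
class SldscFit:
    """Result of one stratified LD score regression."""

    table: pd.DataFrame  # per-annotation coefficients and enrichment
    intercept: float
    h2_total: float

    def annotation(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _fit_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    xw = X * w[:, None]
    return np.linalg.solve(xw.T @ X, xw.T @ y)


def _derive(tau: np.ndarray, counts: np.ndarray, cross: np.ndarray, m: int):
    """Heritability share and enrichment per annotation from coefficients.

    ``counts``: SNPs per annotation; ``cross``: A'A co-membership counts;
    ``m``: total SNPs. h2(C) = sum_C' tau_C' |A_C ∩ A_C'|; total
    h2 = counts . tau.
    """
    h2_cat = cross @ tau
    h2_tot = counts @ tau
    prop_h2 = h2_cat / h2_tot if h2_tot != 0 else np.full_like(h2_cat, np.nan)
    prop_snps = counts / m
    enrich = prop_h2 / prop_snps
    return prop_h2, enrich, h2_tot


def fit_sldsc(
    chisq: np.ndarray,
    ld: pd.DataFrame,
    n_gwas: np.ndarray,
    annot: pd.DataFrame,
    n_blocks: int = DEFAULT_N_BLOCKS,
    include_base: bool = True,
) -> SldscFit:
    """Jointly regress chi-square on N-scaled stratified LD scores.

    The design is ``[1, N * l(j, C)]`` over all annotations (including the
    base); weights are ``1 / max(l(j, base), 1)`` as a heteroscedasticity
    and overcounting proxy. A delete-one block jackknife over ``n_blocks``
    contiguous SNP blocks yields coefficient and enrichment standard
    errors; the coefficient z is one-sided (enrichment above background),
    the enrichment p two-sided against enrichment = 1.

    ``include_base=False`` drops the base column from the design (its LD
    score still sets the weights): required when the other annotations
    partition the SNPs exhaustively, since base would then be an exact
    linear combination of them.
    """
    chisq = np.asarray(chisq, dtype=float)
    n_gwas = np.asarray(n_gwas, dtype=float)
    m = len(chisq)
    if n_blocks > m:
        raise ValueError("more jackknife blocks than SNPs")
    if "base" not in ld.columns:
        raise ValueError("LD score table must include the base annotation")
    base_ld = ld["base"].to_numpy(float)
    names = [c for c in ld.columns if include_base or c != "base"]
    L = ld[names].to_numpy(float)
    A = annot[names].to_numpy(float)
    X = np.column_stack([np.ones(m), n_gwas[:, None] * L])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "singular design: annotations are collinear "
            f"(rank {rank} < {X.shape[1]}); columns: {['intercept'] + names}"
        )
    counts = A.sum(axis=0)
    cross = A.T @ A

    # two-pass weighting: start from the overcounting proxy 1/max(l_base, 1),
    # then divide by the squared per-SNP predicted mean of the first-pass
    # fit, since Var(chi2_j) ~ 2 E[chi2_j]^2 under the regression model
    w = 1.0 / np.maximum(base_ld, 1.0)
    first = _fit_wls(X, chisq, w)
    pred = np.maximum(X @ first, 1.0)
    w = w / pred**2

    coefs = _fit_wls(X, chisq, w)
    tau = coefs[1:]
    prop_h2, enrich, h2_tot = _derive(tau, counts, cross, m)

    # delete-one-block jackknife
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    tau_del = np.empty((n_blocks, len(names)))
    enr_del = np.empty((n_blocks, len(names)))
    prop_del = np.empty((n_blocks, len(names)))
    for b in range(n_blocks):
        keep = np.ones(m, dtype=bool)
        keep[edges[b]:edges[b + 1]] = False
        cb = _fit_wls(X[keep], chisq[keep], w[keep])
        tau_del[b] = cb[1:]
        prop_del[b], enr_del[b], _ = _derive(cb[1:], counts, cross, m)

    def jk_se(dels):
        return np.sqrt((n_blocks - 1) / n_blocks
                       * ((dels - dels.mean(axis=0)) ** 2).sum(axis=0))

    tau_se = jk_se(tau_del)
    enr_se = jk_se(enr_del)
    prop_se = jk_se(prop_del)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_z = np.where(tau_se > 0, tau / tau_se, np.nan)
        enr_z = np.where(enr_se > 0, (enrich - 1.0) / enr_se, np.nan)
    enr_p = 2 * stats.norm.sf(np.abs(enr_z))

    table = pd.DataFrame({
        "tau": tau,
        "tau_se": tau_se,
        "tau_z": tau_z,
        "prop_h2": prop_h2,
        "prop_h2_se": prop_se,
        "prop_snps": counts / m,
        "enrichment": enrich,
        "enrichment_se": enr_se,
        "enrichment_ci_lo": enrich - 1.959964 * enr_se,
        "enrichment_ci_hi": enrich + 1.959964 * enr_se,
        "enrichment_p": enr_p,
    }, index=pd.Index(names, name="annotation"))
    if "base" in table.index:
        # the base covers every SNP: enrichment is 1 by definition
        table.loc["base", ["enrichment", "enrichment_p"]] = [1.0, 1.0]
    return SldscFit(table=table, intercept=float(coefs[0]),
                    h2_total=float(h2_tot))


def enrichment_heatmap_table(fits: dict[tuple, SldscFit]) -> pd.DataFrame:
    """Long-format -log10(q) table across (disease, cell type, category).

    BH correction is recomputed across the whole grid; annotations with a
    negative coefficient z-score are reported as nonsignificant with a
    score of 0.0. The base annotation is excluded.
    """
    rows = []
    for (disease, cell_type), fit in fits.items():
        for name, r in fit.table.iterrows():
            if name == "base":
                continue
            rows.append({
                "disease": disease,
                "cell_type": cell_type,
                "category": name,
                "enrichment": r["enrichment"],
                "enrichment_p": r["enrichment_p"],
                "tau_z": r["tau_z"],
            })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no fits supplied")
    df["q"] = multipletests(df["enrichment_p"].fillna(1.0), method="fdr_bh")[1]
    score = -np.log10(df["q"])
    score[df["tau_z"] < 0] = 0.0
    df["neg_log10_q"] = score
    return df
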