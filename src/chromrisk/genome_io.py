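"""Coordinate types and readers/writers for genomic inputs and outputs.

All coordinates are BED-style: 0-based, half-open ``[start, end)``. Input
dialects that use other conventions are converted at the boundary. Two
intervals overlap iff they share at least one base pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``chrom:[start, end)``.

    Strand defaults to '.' (unstranded), the convention for peaks and bins.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Loop:
    """One chromatin interaction: two anchor bins plus an interaction FDR."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")


def _anchor_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


@dataclass
class LoopSet:
    """Unordered anchor-bin pairs at a fixed resolution.

    Pairs are stored canonically (lexicographically smaller anchor first);
    duplicate canonical pairs are collapsed keeping the minimum FDR.
    """

    loops: list[Loop]
    resolution: int = 5000
    cell_type: str = ""

    @classmethod
    def from_pairs(
        cls,
        pairs: list[tuple[GenomicInterval, GenomicInterval, float]],
        resolution: int = 5000,
        cell_type: str = "",
    ) -> "LoopSet":
        best: dict[tuple, Loop] = {}
        for a, b, fdr in pairs:
            for iv in (a, b):
                if iv.width != resolution:
                    raise ValueError(
                        f"anchor width {iv.width} != resolution {resolution} "
                        f"for {iv.chrom}:{iv.start}-{iv.end}"
                    )
            if _anchor_key(b) < _anchor_key(a):
                a, b = b, a
            key = (_anchor_key(a), _anchor_key(b))
            loop = Loop(a, b, fdr)
            if key not in best or fdr < best[key].fdr:
                best[key] = loop
        loops = [best[k] for k in sorted(best)]
        return cls(loops=loops, resolution=resolution, cell_type=cell_type)

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)

    def anchors(self) -> list[GenomicInterval]:
        """Distinct anchor bins, sorted."""
        seen = {}
        for lp in self.loops:
            for iv in (lp.anchor_a, lp.anchor_b):
                seen[_anchor_key(iv)] = iv
        return [seen[k] for k in sorted(seen)]


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/-, got {self.strand!r}")


@dataclass
class GeneModel:
    """Isoform-level gene model: per-transcript TSS and exon intervals."""

    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript_ids in gene model")

    @property
    def gene_ids(self) -> list[str]:
        out, seen = [], set()
        for t in self.transcripts:
            if t.gene_id not in seen:
                seen.add(t.gene_id)
                out.append(t.gene_id)
        return out

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.gene_id == gene_id]

    def tss_sites(self) -> list[tuple[str, int]]:
        """All (chrom, tss) pairs across transcripts."""
        return [(t.chrom, t.tss) for t in self.transcripts]

    def gene_body(self, gene_id: str) -> GenomicInterval:
        """Span from min to max exon coordinate over the gene's transcripts."""
        txs = self.transcripts_of(gene_id)
        if not txs:
            raise KeyError(gene_id)
        start = min(e.start for t in txs for e in t.exons)
        end = max(e.end for t in txs for e in t.exons)
        return GenomicInterval(txs[0].chrom, start, end)

    def exon_intervals(self) -> list[tuple[str, GenomicInterval]]:
        """(gene_id, exon) pairs over all transcripts."""
        return [(t.gene_id, e) for t in self.transcripts for e in t.exons]


@dataclass
class SummaryStats:
    """Per-SNP GWAS summary statistics.

    Columns: snp, chrom, bp, a1, a2, z, p, n, info, maf. ``z`` is the signed
    association Z-score; ``p`` the two-sided p-value.
    """

    table: pd.DataFrame

    REQUIRED = ("snp", "chrom", "bp", "a1", "a2", "z", "p", "n", "info", "maf")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats missing columns: {missing}")
        p = self.table["p"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (self.table["n"] <= 0).any():
            raise ValueError("per-SNP N must be positive")
        if (self.table["maf"] > 0.5).any() or (self.table["maf"] < 0).any():
            raise ValueError("MAF must lie in [0, 0.5]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSnpMap:
    """Gene -> ordered SNP-ID assignments plus the gene span for output."""

    snps: dict[str, list[str]] = field(default_factory=dict)
    spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def add(self, gene_id: str, snp_id: str) -> None:
        lst = self.snps.setdefault(gene_id, [])
        if snp_id not in lst:
            lst.append(snp_id)

    def genes(self) -> list[str]:
        return sorted(self.snps)

    def union(self, other: "GeneSnpMap") -> "GeneSnpMap":
        out = GeneSnpMap()
        for src in (self, other):
            for g, ids in src.snps.items():
                for s in ids:
                    out.add(g, s)
        for src in (self, other):
            for g, span in src.spans.items():
                if g in out.spans:
                    c, lo, hi = out.spans[g]
                    out.spans[g] = (c, min(lo, span[1]), max(hi, span[2]))
                else:
                    out.spans[g] = span
        return out

    def restrict_to_panel(self, snp_ids) -> tuple["GeneSnpMap", int]:
        """Drop SNP IDs absent from a panel; return new map + dropped count."""
        keep = set(snp_ids)
        out = GeneSnpMap()
        dropped = 0
        for g, ids in self.snps.items():
            kept = [s for s in ids if s in keep]
            dropped += len(ids) - len(kept)
            if kept:
                out.snps[g] = kept
                if g in self.spans:
                    out.spans[g] = self.spans[g]
        if dropped:
            logger.info("dropped %d SNP assignments absent from panel", dropped)
        return out, dropped

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSnpMap):
            return NotImplemented
        mine = {g: sorted(v) for g, v in self.snps.items()}
        theirs = {g: sorted(v) for g, v in other.snps.items()}
        return mine == theirs


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file (>= 3 tab-delimited columns) into sorted intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bedpe_loops(path, resolution: int = 5000, cell_type: str = "") -> LoopSet:
    """Read a BEDPE-with-FDR loop file (chromA startA endA chromB startB endB fdr)."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                fdr = float(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= fdr <= 1.0:
                raise ValueError(f"{path}:{lineno}: fdr {fdr} outside [0, 1]")
            pairs.append((a, b, fdr))
    return LoopSet.from_pairs(pairs, resolution=resolution, cell_type=cell_type)


def write_bedpe_loops(loops: LoopSet, path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{lp.fdr:.6g}\n"
            )


def read_gene_model(path) -> GeneModel:
    """Read the gene-model TSV.

    Columns: gene_id, transcript_id, chrom, strand, tss, exon_starts,
    exon_ends (the last two comma-separated lists).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "gene_id", "transcript_id", "chrom", "strand", "tss",
        "exon_starts", "exon_ends",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene model missing columns: {missing}")
    txs = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise ValueError(f"{row.transcript_id}: exon list lengths differ")
        exons = tuple(
            GenomicInterval(row.chrom, s, e, row.strand)
            for s, e in zip(starts, ends)
        )
        txs.append(
            Transcript(row.gene_id, row.transcript_id, row.chrom, row.strand,
                       int(row.tss), exons)
        )
    return GeneModel(txs)


def write_gene_model(genes: GeneModel, path) -> None:
    rows = []
    for t in genes.transcripts:
        rows.append({
            "gene_id": t.gene_id,
            "transcript_id": t.transcript_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "tss": t.tss,
            "exon_starts": ",".join(str(e.start) for e in t.exons),
            "exon_ends": ",".join(str(e.end) for e in t.exons),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_SUMSTAT_ALIASES = {
    "snp": "snp", "rsid": "snp", "markername": "snp",
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "bp": "bp", "pos": "bp", "position": "bp",
    "a1": "a1", "a2": "a2", "effect_allele": "a1", "other_allele": "a2",
    "z": "z", "zscore": "z", "p": "p", "pval": "p", "p_value": "p",
    "beta": "beta", "or": "or_", "n": "n", "nsum": "n",
    "info": "info", "maf": "maf", "frq": "maf",
}


def read_sumstats(path, default_n: float | None = None) -> SummaryStats:
    """Read a GWAS summary-statistics TSV.

    Requires SNP/CHR/BP/A1/A2 and at least one of Z or (P plus a signed
    effect column BETA or OR). Missing Z is derived via
    ``z = sign * Phi^{-1}(1 - p/2)``; missing P via the reverse. Missing N
    is filled with ``default_n`` (and logged) when given, else an error.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [_SUMSTAT_ALIASES.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    for col in ("snp", "chrom", "bp", "a1", "a2"):
        if col not in df.columns:
            raise ValueError(f"sumstats missing required column {col.upper()}")
    has_z = "z" in df.columns
    has_p = "p" in df.columns
    if not has_z and not has_p:
        raise ValueError("sumstats must carry Z or P")
    if not has_z:
        if "beta" in df.columns:
            sign = np.sign(df["beta"].to_numpy(float))
        elif "or_" in df.columns:
            sign = np.sign(np.log(df["or_"].to_numpy(float)))
        else:
            raise ValueError("P without a signed effect column (BETA/OR)")
        sign = np.where(sign == 0, 1.0, sign)
        df["z"] = sign * stats.norm.isf(df["p"].to_numpy(float) / 2)
    if not has_p:
        df["p"] = 2 * stats.norm.sf(np.abs(df["z"].to_numpy(float)))
    df["p"] = np.clip(df["p"].to_numpy(float), np.nextafter(0, 1), 1.0)
    if "n" not in df.columns or df["n"].isna().any():
        if default_n is None:
            raise ValueError("sumstats lack N and no default_n was given")
        filled = df["n"].isna().sum() if "n" in df.columns else len(df)
        logger.info("filled N for %d SNPs with constant %s", filled, default_n)
        if "n" in df.columns:
            df["n"] = df["n"].fillna(default_n)
        else:
            df["n"] = default_n
    if "info" not in df.columns:
        df["info"] = 1.0
    if "maf" not in df.columns:
        df["maf"] = np.nan
    df["chrom"] = df["chrom"].astype(str)
    keep = ["snp", "chrom", "bp", "a1", "a2", "z", "p", "n", "info", "maf"]
    return SummaryStats(df[keep].reset_index(drop=True))


def write_sumstats(ss: SummaryStats, path) -> None:
    df = ss.table.rename(columns={
        "snp": "SNP", "chrom": "CHR", "bp": "BP", "a1": "A1", "a2": "A2",
        "z": "Z", "p": "P", "n": "N", "info": "INFO", "maf": "MAF",
    })
    df.to_csv(path, sep="\t", index=False)


def write_magma_annot(gmap: GeneSnpMap, path) -> int:
    """Write the standard ``.genes.annot`` dialect.

    One line per gene: gene_id, TAB, chrom:start:stop, TAB-separated SNP IDs.
    Genes with zero SNPs are omitted (count returned and logged).
    """
    if not gmap.snps:
        raise ValueError("refusing to write an empty gene-SNP map")
    omitted = 0
    with open(path, "w") as fh:
        for gene in gmap.genes():
            ids = gmap.snps[gene]
            if not ids:
                omitted += 1
                continue
            chrom, lo, hi = gmap.spans.get(gene, ("NA", 0, 0))
            fh.write(f"{gene}\t{chrom}:{lo}:{hi}\t" + "\t".join(ids) + "\n")
    if omitted:
        logger.info("omitted %d genes with zero SNPs", omitted)
    return omitted


def read_magma_annot(path) -> GeneSnpMap:
    gmap = GeneSnpMap()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            gene, span = fields[0], fields[1]
            chrom, lo, hi = span.split(":")
            gmap.snps[gene] = list(fields[2:])
            gmap.spans[gene] = (chrom, int(lo), int(hi))
    return gmap
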