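# Methods

This note documents the models, conventions and numerical choices behind
`chromrisk`. The package links noncoding GWAS variants to genes through
cell-type chromatin interactomes (PLAC-seq-style loop maps), tests genes
with an LD-aware quadratic-form statistic, partitions SNP heritability
across loop-derived annotations, and scores cell-type and pathway
enrichment of the resulting risk-gene lists. Everything runs end-to-end on
a synthetic-data generator so that each stage can be validated against
ground truth without external downloads.

## Coordinates and overlap

All genomic coordinates are BED-style 0-based half-open `[start, end)`;
1-based input dialects are converted at the boundary. Two intervals
overlap iff they share at least one base pair. Loop anchor pairs are
unordered; the canonical stored form puts the lexicographically smaller
anchor first, and duplicate canonical pairs collapse to the record with
the smallest interaction FDR (source data do not specify a duplicate rule;
minimum-FDR keeps the strongest evidence).

## Loop classification

Anchor bins (5 kb by default) are labeled against H3K4me3, H3K27ac and
ATAC peak sets and the isoform-level TSS list:

- **promoter** — overlaps an H3K4me3 *and* an H3K27ac peak and lies within
  2,000 bp of a TSS (minimum distance from any bin base to any TSS, the
  most permissive reading);
- **enhancer** — overlaps an H3K27ac peak that is itself more than
  2,000 bp from every TSS;
- **promoter/enhancer** — qualifies for both of the above;
- **H3K4me3 (distal)** — overlaps H3K4me3 without a promoter call;
- **ATAC-only** — overlaps an ATAC peak and is devoid of both histone
  marks;
- **other** — residual.

Label precedence is promoter/enhancer > promoter > enhancer > H3K4me3 >
ATAC-only > other. Loops map to eight categories (promoter-to-enhancer,
-promoter, -ATAC, -promoter/enhancer, -other; H3K4me3-to-H3K4me3,
-to-other; other). Enhancer–enhancer and enhancer–H3K4me3 pairs are not
named classes; under the precedence rules they fall into "other" and
"H3K4me3-to-other" respectively. Category counts always partition the
loop set. Distance summaries use anchor-midpoint separations of
cis promoter-to-enhancer loops; trans-chromosomal pairs are excluded from
distances only and counted.

## SNP-to-gene annotation

Promoters span 1.5 kb upstream to 500 bp downstream of each isoform TSS,
strand-aware and clipped at position 0. Loops are filtered to interaction
FDR < 0.01 with at least one anchor on a promoter. Exonic and promoter
SNPs are assigned positionally to their host genes (multi-gene assignment
allowed — isoforms overlap). Intronic/intergenic SNPs — those inside no
promoter or exon of any gene — are assigned through loops: the SNP must
sit in an anchor bin overlapping an enhancer region, and the partner
anchor must overlap a promoter or exon of the target gene. Subset modes:
`positional_only` restricts positional assignments to SNPs inside
promoter/exon-overlapping anchor bins of the filtered loops (a flag
switches to genome-wide positional assignment, since the narrower reading
of the subset analysis is ambiguous); `enhancer_only` keeps the
interactional route alone; `window10kb` assigns every SNP within 10 kb of
a gene body. The `.genes.annot` output uses the standard MAGMA dialect;
each gene's span is the min/max over its promoter and exon coordinates,
falling back to the gene body. Loop downsampling (used to equalize loop
numbers across cell types) is a seeded uniform sample without
replacement, run as `n_iter` iterations with seeds `seed+0 .. seed+n-1`.

## Gene-level association

The gene statistic is `T = sum_j z_j^2` over the gene's SNPs ("SNP-wise
mean" family; the sum is scale-equivalent to the mean at fixed SNP
count). Under the null, `z ~ N(0, R)` with `R` the reference-panel LD
correlation matrix, so `T` is a quadratic form distributed as
`sum_i lambda_i chi2_1` with `lambda` the eigenvalues of `R`. Tail
probabilities come from Imhof's characteristic-function inversion,
evaluated by vectorized composite Simpson quadrature: the integral is
truncated where its envelope drops below 1e-11 and the step resolves the
oscillation period (16 points per cycle). When all retained eigenvalues
are equal the scaled chi-square closed form is used (exact for identity
LD and for fully degenerate LD); a Satterthwaite–Welch moment-matched
chi-square is the fallback if the grid would be excessive or the result
non-finite. Eigenvalues below `1e-10 * max` are discarded; indefinite
matrices get a 1e-6 ridge and negative eigenvalues truncate at 0.
P-values are floored at 1e-300. This is a faithful implementation of the
stated statistic with an eigenvalue null, not a bit-compatible clone of
any released tool (no permutation/approximation internals are
reproduced). Benjamini–Hochberg correction is applied within each run
(one disease × cell type × mode), significance at q < 0.05; top-gene sets
use uncorrected p against fixed thresholds (5e-8, or 5e-12 for the
highest-powered study). Per-SNP sample sizes are consumed for reporting
and for the heritability regression; the statistic itself uses Z only,
which already embeds N.

Summary-statistic QC drops records with non-positive SE (when present)
and SNPs whose N exceeds the mean by more than 5 SD, removes X/Y/MT, and
keeps indels and multiallelic records. The LD-score munging stage
additionally drops INFO <= 0.9, MAF <= 0.01, strand-ambiguous alleles
(A/T, C/G), duplicate IDs, and restricts to a configured well-imputed SNP
list when one is supplied (the stand-in for a HapMap3 restriction).

## Stratified LD score regression

Per-SNP chi-square statistics are regressed jointly on annotation-
stratified LD scores, `E[chi2_j] = N sum_C tau_C l(j,C) + 1`.
LD scores use bias-corrected squared correlations,
`r2_adj = r2 - (1 - r2)/(n - 2)`, summed within a base-pair window
(default 1 Mb; 200 kb in the toy pipeline). A base-pair window replaces
the genetic-map window of real analyses because toy genomes carry no
recombination map; this is the main documented divergence. The annotation
set is a small configurable baseline (an all-ones base plus the
loop-derived categories: total bins, promoter, enhancer, and their union)
rather than a full released baseline model; arbitrary annotation matrices
are accepted.

Weighted least squares uses two passes: first `1/max(l_base, 1)`
(overcounting proxy), then division by the squared per-SNP predicted mean
of the first-pass fit, since `Var(chi2_j) ≈ 2 E[chi2_j]^2` under the
model. The second pass matters: without it, jackknife confidence
intervals for enrichment are measurably anticonservative (about 90%
realized coverage at nominal 95% in simulation); with it, realized
coverage matches nominal.

Heritability shares derive from the coefficients:
`h2(C) = sum_C' tau_C' |A_C ∩ A_C'|`, total `h2 = counts · tau`,
enrichment = share of h2 over share of SNPs. Across a disjoint exhaustive
partition the shares sum to 1 identically (when fitting a partition, the
base column must be excluded from the design — it is their exact sum —
via `include_base=False`; its LD score still sets the weights). Standard
errors come from a delete-one block jackknife over contiguous equal-count
SNP blocks (default 200; 100 in the toy runs; block boundaries are wider
than the generator's LD blocks, so blocks are effectively independent).
The coefficient z is `tau/se`; enrichment p is two-sided normal against
enrichment = 1. In the cross-disease/cell-type summary table, BH runs
across the whole grid and annotations with a negative coefficient z are
reported as nonsignificant with a -log10(q) score of 0.0.

## Cell-type enrichment (EWCE-style)

Specificity is each gene's mean expression in a cell type divided by the
sum of its means across cell types; all-zero genes are dropped. The
observed score of a gene list is its summed specificity per cell type
(equivalent to the mean up to a constant at fixed list size). The null is
`n_boot` (default 10,000) random gene lists of the same size drawn
uniformly without replacement — no expression-level matching (the
level-matched variant is not implemented; bootstrap sampling is uniform).
The empirical p is the mid-p
`(1 + #{boot > obs} + 0.5 #{boot == obs}) / (n_boot + 1)`, never below
`1/(n_boot + 1)`. Ties are counted half deliberately: specificity
matrices with blocks of identical rows (exactly what the synthetic
generator produces, and common after thresholding real data) tie
frequently, and the plain `>=` convention is then conservative —
measurably non-uniform under the null — while the mid-p is calibrated.
Enrichment z is `(obs - mean)/sd` of the bootstrap; significance at
p < 0.05.

## Pathway over-representation

The ORA stage is a hypergeometric upper tail `P(X >= k)` with the
configured gene universe as population, each pathway as the success set
and the target list as the draw, BH-corrected across pathways
(q < 0.05). The input gene ordering (e.g. by association z-score) is
accepted but ignored — an ordered-query correction is not implemented;
this is a documented divergence from ordered-mode web tools. Pathways
with identical gene sets are collapsed to a single representative; the
default keeps the one with the *highest* BH-corrected p (the printed
convention of the workflow this mirrors, surprising as it is), with a
flag to keep the lowest instead; non-representatives are flagged, not
deleted.

## Synthetic-data generator

The generator is a pure function of `SimConfig` (root seed included);
per-stage streams derive deterministically from the root seed, so stages
are independently reproducible.

**Genome.** Chromosomes are tiled with 12-bin units, interleaved
round-robin across chromosomes; each unit carries two genes (one plain
promoter bin, one promoter bin that also holds a distal H3K27ac peak),
three enhancer bins, two distal-H3K4me3 bins, one ATAC-only bin and
unmarked bins. Genes have 1–3 isoforms (TSS jitter <= 100 bp), two exons
each, alternating strand. Loops wire the unit so that promoter-to-
enhancer pairs form the majority (~54% of loops, comparable to real
microglia PLAC-seq maps) and all eight categories appear. Loop FDRs are
drawn below 0.01 with probability `loop_sig_fraction` (default 0.9),
otherwise in (0.011, 0.5).

**LD panel.** SNPs sit on an even grid with jitter; consecutive SNPs form
AR(1) blocks (`ld_rho^|i-j|`, default rho 0.7, block size 10),
independent across blocks and chromosomes. Dosages are Gaussian with mean
`2f` and variance `2f(1-f)` for an allele frequency `f ~ U(0.10, 0.45)`:
the AR(1) correlation is then exact at every sample size, which discrete
genotypes would attenuate. Consequences: no allele-frequency/LD coupling,
no hard {0,1,2} dosages, no population structure — tests validate the
statistical machinery, not robustness to genotype discreteness.

**GWAS.** Per-SNP effect variances put each named annotation's share of
`h2_total` (default 0.4, GWAS N 50,000) uniformly on its member SNPs and
the remainder on the rest, so annotation enrichments are exact by
construction. Marginal scores are `Z = sqrt(N) R beta + L eps` computed
blockwise with the panel's *empirical* LD (Cholesky of the empirical
block correlation), so the heritability regression and the gene test see
exactly the LD that generated the data; `E[chi2] = N sum_k r2_jk
sigma2_k + 1` holds by construction.

**Expression.** Each cell type gets `n_marker_genes` markers elevated
`marker_fold`-fold (default 10) over a gene-specific flat baseline;
non-marker genes are expressed uniformly across cell types. This yields
exact specificity values (markers 10/13 in their type at 4 cell types)
and many ties — which is why the EWCE p uses a mid-p.

What passing tests on these data do show: correct interval logic and
classification, exact annotation construction, calibrated null
distributions under known LD, recovery of planted heritability
enrichment, calibrated and powered cell-type enrichment. What they do not
show: behavior under real LD structure, allele-frequency spectra,
genotype discreteness, imputation error, or single-cell noise.

## Problem sizes and defaults

The shipped defaults are sized so the full validation battery runs in
minutes on one CPU: toy genomes of 2 × 2 Mb at 5 kb resolution with
12–50 genes; LD panels of 400–4,000 SNPs × 50–2,000 samples; gene-test
calibration on 400 single-block genes per replicate; heritability
recovery on 4,000 SNPs × 600 samples × 20 replicates with 100 jackknife
blocks; EWCE calibration with 1,000 target draws × 200 bootstraps
(10,000 bootstraps for single power analyses). The pipeline defaults
mirror the analysis conventions (loop FDR 0.01, 60,000-loop downsampling
× 10, gene q < 0.05, top-gene thresholds 5e-8 / 5e-12); `toy_config()`
scales the downsampling and bootstrap counts to the synthetic genome.

## Known limitations

- Base-pair LD windows instead of genetic-map windows; no centiMorgan
  support.
- Small configurable baseline instead of a released multi-category
  baseline model; results on real data would require the full baseline.
- The gene test reproduces the stated statistic, not any tool's internal
  approximations; p-values will differ in detail from released binaries.
- Bootstrap gene sampling in EWCE is uniform; no expression-level
  matching.
- The ORA stage is unordered hypergeometric + BH; no ordered-query or
  graph-structured multiple-testing correction.
- Trans-chromosomal loops are retained everywhere except distance
  summaries; the synthetic generator never produces them.
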