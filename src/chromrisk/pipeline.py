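"""End-to-end orchestration: simulate -> classify -> annotate -> test ->
partitioned heritability -> cell-type and pathway enrichment -> overlaps.

A single flat config drives every stage; all randomness derives from one
root seed, and a run manifest records the config hash, child seeds and
output checksums so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annot as annot_mod
from . import enrichment as enr_mod
from . import geneassoc, loops as loops_mod, sldsc as sldsc_mod
from . import simulate as sim_mod
from .genome_io import write_bed, write_bedpe_loops, write_gene_model, write_magma_annot, write_sumstats

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

# stage parameter defaults follow the study conventions: loop FDR 0.01,
# promoter-anchored filtering, 60,000-loop downsampling repeated 10 times,
# gene FDR 0.05, top-gene thresholds 5e-8 / 5e-12
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "chromrisk_run",
    "simulate": {},  # SimConfig overrides; empty dict = defaults
    "fdr_max": 0.01,
    "downsample_n": 60_000,
    "downsample_iters": 10,
    "gene_q": 0.05,
    "top_threshold": 5e-8,
    "top_threshold_strict": 5e-12,
    "nboot": 10_000,
    "window_bp": 1_000_000,
    "jackknife_blocks": 200,
    "h2_annotation": "total",
    "h2_share": 0.5,
}


def toy_config(seed: int = 0) -> dict:
    """A configuration sized for the synthetic study (minutes, one CPU)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg.update({
        "seed": seed,
        "downsample_n": 100,
        "downsample_iters": 5,
        "nboot": 1000,
        "jackknife_blocks": 50,
        "window_bp": 200_000,
    })
    return cfg


def load_config(path) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if key == "simulate" and isinstance(value, dict):
            cfg["simulate"].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """All invariant violations at once; an empty list means valid."""
    problems = []
    if not 0 < cfg.get("fdr_max", 0) <= 1:
        problems.append(f"fdr_max must lie in (0, 1], got {cfg.get('fdr_max')}")
    for key in ("top_threshold", "top_threshold_strict", "gene_q"):
        if not cfg.get(key, 0) > 0:
            problems.append(f"{key} must be positive, got {cfg.get(key)}")
    for key in ("downsample_n", "downsample_iters", "nboot",
                "jackknife_blocks", "window_bp"):
        if not cfg.get(key, 0) >= 1:
            problems.append(f"{key} must be >= 1, got {cfg.get(key)}")
    if "simulate" not in cfg and not cfg.get("loops"):
        problems.append("config needs a simulate block or a loops path")
    if not 0 <= cfg.get("h2_share", 0) <= 1:
        problems.append(f"h2_share must lie in [0, 1], got {cfg.get('h2_share')}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Execute every stage in dependency order; return the run manifest.

    Outputs are written as TSV/JSON under the configured output directory;
    a failure in any stage aborts the run with the stage named.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "stages": [],
        "checksums": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)

    stage = "simulate"
    try:
        sim = sim_mod.SimConfig(seed=seed, **cfg.get("simulate", {}))
        genes, peaks, loop_set = sim_mod.simulate_genome(sim)
        panel = sim_mod.simulate_ld_panel(sim)
        expr = sim_mod.simulate_expression(sim)
        gene_path = out / "genes.tsv"
        write_gene_model(genes, gene_path)
        loops_path = out / "loops.bedpe"
        write_bedpe_loops(loop_set, loops_path)
        for name, ivs in peaks.items():
            write_bed(ivs, out / f"{name}.bed")
        expr.to_csv(out / "expression.tsv", sep="\t")
        record(stage, gene_path, loops_path, out / "expression.tsv",
               *(out / f"{n}.bed" for n in peaks))

        stage = "classify-loops"
        labels = loops_mod.label_anchors(
            loop_set, peaks["h3k4me3"], peaks["h3k27ac"], peaks["atac"], genes
        )
        cats = loops_mod.category_counts(loop_set, labels)
        deg = loops_mod.degree_distributions(loop_set, labels)
        dist = loops_mod.distance_stats(loop_set, labels)
        summary = {
            "categories": cats,
            "enhancers_per_promoter": dict(deg[0]),
            "promoters_per_enhancer": dict(deg[1]),
            "distance_summary": dist["summary"],
        }
        cls_path = out / "loop_summary.json"
        cls_path.write_text(json.dumps(summary, indent=2, default=float))
        record(stage, cls_path)

        stage = "simulate-gwas"
        bin_sets = sldsc_mod.category_bin_sets(loop_set, labels)
        annot_matrix = sldsc_mod.bins_to_annotations(bin_sets, panel.snps)
        target = cfg["h2_annotation"]
        sim_gwas = copy.copy(sim)
        sim_gwas.enrichment_spec = {target: cfg["h2_share"]}
        masks = {c: annot_matrix[c].to_numpy(bool) for c in annot_matrix.columns
                 if c != "base"}
        ss, truth = sim_mod.simulate_gwas(panel, masks, sim_gwas)
        ss_path = out / "sumstats.tsv"
        write_sumstats(ss, ss_path)
        record(stage, ss_path)

        stage = "build-annot"
        ss_qc, qc_report = geneassoc.qc_sumstats(ss)
        enhancer_regions = [
            iv for iv in bin_sets["enhancer"]
        ]
        maps = {}
        for mode in ("full", "positional_only", "enhancer_only", "window10kb"):
            gmap = annot_mod.build_annotation(
                mode, ss_qc, genes, loops=loop_set,
                enhancers=enhancer_regions, fdr_max=cfg["fdr_max"],
            )
            maps[mode] = gmap
            if gmap.snps:
                write_magma_annot(gmap, out / f"annot_{mode}.genes.annot")
        record(stage, *(out / f"annot_{m}.genes.annot" for m in maps
                        if maps[m].snps))

        stage = "gene-assoc"
        results = {}
        for mode, gmap in maps.items():
            if not gmap.snps:
                continue
            res = geneassoc.run_gene_tests(gmap, ss_qc, panel,
                                           alpha=cfg["gene_q"])
            res.to_csv(out / f"genes_{mode}.tsv", sep="\t", index=False)
            results[mode] = res
        record(stage, *(out / f"genes_{m}.tsv" for m in results))

        stage = "downsample"
        n_down = min(cfg["downsample_n"], len(loop_set))
        down_counts = []
        for it in range(cfg["downsample_iters"]):
            sub = annot_mod.downsample_loops(loop_set, n_down, seed + it)
            gmap = annot_mod.build_annotation(
                "full", ss_qc, genes, loops=sub,
                enhancers=enhancer_regions, fdr_max=cfg["fdr_max"],
            )
            if not gmap.snps:
                down_counts.append(0)
                continue
            res = geneassoc.run_gene_tests(gmap, ss_qc, panel,
                                           alpha=cfg["gene_q"])
            down_counts.append(int(res["significant"].sum()))
        down_path = out / "downsample.json"
        down_path.write_text(json.dumps({
            "n_loops": n_down,
            "iterations": cfg["downsample_iters"],
            "significant_gene_counts": down_counts,
            "mean": float(np.mean(down_counts)),
            "sd": float(np.std(down_counts, ddof=1)) if len(down_counts) > 1
            else 0.0,
        }, indent=2))
        record(stage, down_path)

        stage = "sldsc"
        ss_m, munge_report = sldsc_mod.munge_for_ldsc(ss_qc)
        keep = ss_m.table["snp"]
        pos = {s: i for i, s in enumerate(panel.snps["snp"])}
        idx = np.array([pos[s] for s in keep])
        sub_panel = sim_mod.Panel(
            genotypes=panel.genotypes[:, idx],
            snps=panel.snps.iloc[idx].reset_index(drop=True),
        )
        sub_annot = annot_matrix.loc[keep]
        ld = sldsc_mod.compute_ld_scores(sub_panel, sub_annot,
                                         window_bp=cfg["window_bp"])
        chisq = ss_m.table["z"].to_numpy() ** 2
        n_blocks = min(cfg["jackknife_blocks"], len(chisq) // 2)
        fit = sldsc_mod.fit_sldsc(
            chisq, ld, ss_m.table["n"].to_numpy(), sub_annot,
            n_blocks=n_blocks,
        )
        fit_path = out / "sldsc.tsv"
        fit.table.to_csv(fit_path, sep="\t")
        heat = sldsc_mod.enrichment_heatmap_table({("sim", "sim"): fit})
        heat.to_csv(out / "sldsc_heatmap.tsv", sep="\t", index=False)
        record(stage, fit_path, out / "sldsc_heatmap.tsv")

        stage = "ewce"
        spec = enr_mod.make_specificity(expr)
        res_full = results["full"]
        sig = list(res_full.loc[res_full["significant"], "gene_id"])
        if len(sig) < enr_mod.MIN_TARGET_GENES:
            sig = list(res_full.nsmallest(10, "p")["gene_id"])
        ewce = enr_mod.ewce_test(sig, spec, n_boot=cfg["nboot"], seed=seed)
        ewce_path = out / "ewce.tsv"
        ewce.to_csv(ewce_path, sep="\t")
        record(stage, ewce_path)

        stage = "ora"
        universe = set(expr.index)
        pathways = {
            f"markers_{ct}": set(sim_mod.marker_genes(sim, ct))
            for ct in expr.columns
        }
        rng = np.random.default_rng(seed + 1000)
        all_genes = sorted(universe)
        for i in range(3):
            pathways[f"random_{i}"] = set(
                rng.choice(all_genes, size=min(10, len(all_genes)),
                           replace=False)
            )
        db = enr_mod.PathwayDB(pathways=pathways, universe=universe)
        ora = enr_mod.ora_test(sig, db)
        ora = enr_mod.collapse_duplicate_pathways(ora, db)
        ora_path = out / "ora.tsv"
        ora.to_csv(ora_path, sep="\t", index=False)
        record(stage, ora_path)

        stage = "overlap"
        sets = {
            mode: geneassoc.top_genes(res, cfg["top_threshold"])
            for mode, res in results.items()
        }
        counts = geneassoc.overlap_counts(sets)
        ov_path = out / "overlap.tsv"
        pd.DataFrame(
            [{"sets": "&".join(k), "count": v} for k, v in sorted(counts.items())]
        ).to_csv(ov_path, sep="\t", index=False)
        record(stage, ov_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["qc_report"] = qc_report
    manifest["munge_report"] = munge_report
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
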