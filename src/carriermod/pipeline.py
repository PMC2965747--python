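"""End-to-end pipeline: QC -> association scan -> top-region selection -> stage-2 fits.

Mirrors a two-stage modifier GWAS: stage-1 genotypes are QC'd and scanned
with the kinship-adjusted score test, the top independent regions (LD-pruned
at r^2 < 0.8, default 79, plus any forced-in confirmed SNPs) are carried to
a stage-2 cohort where hazard ratios are estimated per stage, combined in a
pooled stage-stratified fit, and cross-checked by fixed-effect meta-analysis.
Optional gene-set enrichment and IBD-sharing stages run when their inputs
are configured.  Every stage appends to a ledger that is written alongside
the result tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .assoc import genome_scan, prepare_scan_inputs
from .cohort import ValidationError, kinship_matrix
from .config import RunConfig
from .enrichment import gene_scores, gsea_p, map_snps_to_genes
from .genotypes import MISSING, GenotypeMatrix
from .hazard import combined_stage_fit, fit_hr, meta_fixed_effect
from .ibd import GeneticMap, detect_segments
from .plink import read_bed_bim_fam, read_ped_map
from .qc import ancestry_outliers, iterative_qc, ld_prune

log = logging.getLogger("carriermod")

__all__ = ["run_pipeline", "load_genotypes"]


def load_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return read_bed_bim_fam(prefix)
    if prefix.with_suffix(".ped").exists():
        return read_ped_map(prefix)
    raise ValidationError(f"no .bed or .ped found for prefix {prefix}")


def _align(gm: GenotypeMatrix, carriers):
    """Intersect genotyped samples with validated carriers, preserving genotype order."""
    by_id = {c.individual_id: c for c in carriers}
    idx = [i for i, s in enumerate(gm.sample_ids) if s in by_id]
    gm = gm.subset(sample_idx=idx)
    kept = [by_id[s] for s in gm.sample_ids]
    return gm, kept


def _stage_data(geno_prefix: str, pheno_path: str, stage: int, cfg: RunConfig, ledger: list):
    gm = load_genotypes(geno_prefix)
    carriers, pedigrees, excluded = cio.read_phenotype_table(pheno_path, stage=stage)
    for iid, reason in excluded:
        log.info("stage %d: excluded %s (%s)", stage, iid, reason)
    ledger.append(
        {
            "stage": stage,
            "step": "phenotype_validation",
            "n_removed": len(excluded),
            "n_remaining": len(carriers),
        }
    )
    gm, carriers = _align(gm, carriers)
    affected = np.asarray([c.affected for c in carriers], dtype=bool)
    gm, report = iterative_qc(gm, cfg.qc, affected=affected)
    for s in report.steps:
        ledger.append(
            {
                "stage": stage,
                "step": s.name,
                "threshold": s.threshold,
                "n_removed": s.n_removed,
                "n_remaining": s.n_remaining,
            }
        )
    if gm.n_snps >= 10 and gm.n_samples >= 10:
        flagged, _ = ancestry_outliers(gm, cutoff=cfg.qc.mds_cutoff)
        keep = [i for i, s in enumerate(gm.sample_ids) if s not in set(flagged)]
        gm = gm.subset(sample_idx=keep)
        ledger.append(
            {
                "stage": stage,
                "step": "ancestry_outliers",
                "threshold": cfg.qc.mds_cutoff,
                "n_removed": len(flagged),
                "n_remaining": gm.n_samples,
            }
        )
    carriers = [c for c in carriers if c.individual_id in set(gm.sample_ids)]
    order = {s: k for k, s in enumerate(gm.sample_ids)}
    carriers.sort(key=lambda c: order[c.individual_id])
    return gm, carriers, pedigrees


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the result bundle and writes files."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ledger: list[dict] = []
    bundle: dict = {"ledger": ledger}

    if cfg.genotypes is None or cfg.phenotypes is None:
        raise ValidationError("stage-1 genotypes and phenotypes are required")
    if cfg.incidence is None:
        raise ValidationError("an incidence-model config is required")
    incidence = cio.read_incidence(cfg.incidence)

    gm1, carriers1, peds1 = _stage_data(cfg.genotypes, cfg.phenotypes, 1, cfg, ledger)
    kin = kinship_matrix(peds1, [c.individual_id for c in carriers1])
    inputs1 = prepare_scan_inputs(carriers1, incidence, kinship=kin)
    keep = [i for i, s in enumerate(gm1.sample_ids) if s in set(inputs1.ids)]
    gm1 = gm1.subset(sample_idx=keep)
    scan = genome_scan(gm1, inputs1)
    bundle["scan"] = scan
    scan.results.to_csv(out_dir / "assoc_stage1.tsv", sep="\t", index=False)
    scan.qq.to_csv(out_dir / "qq_stage1.tsv", sep="\t", index=False)
    (out_dir / "lambda.txt").write_text(f"{scan.lambda_gc:.6f}\n")
    log.info("stage 1 scan: %d SNPs, lambda = %.3f", len(scan.results), scan.lambda_gc)

    # top independent regions, plus forced-in confirmed SNPs
    pvals = scan.results["p"].to_numpy(dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    kept_idx = ld_prune(gm1, pvals, r2_max=cfg.ld_prune_r2, top_k=cfg.top_k_regions)
    top_snps = list(scan.results["snp"].iloc[kept_idx])
    for s in cfg.forced_snps:
        if s not in top_snps and s in set(scan.results["snp"]):
            top_snps.append(s)
    bundle["top_snps"] = top_snps
    (out_dir / "top_regions.txt").write_text("\n".join(top_snps) + "\n")

    if cfg.genotypes2 and cfg.phenotypes2:
        gm2, carriers2, _ = _stage_data(cfg.genotypes2, cfg.phenotypes2, 2, cfg, ledger)
        inputs2 = prepare_scan_inputs(carriers2, incidence)
        keep2 = [i for i, s in enumerate(gm2.sample_ids) if s in set(inputs2.ids)]
        gm2 = gm2.subset(sample_idx=keep2)
        rows = []
        snp_pos1 = {s: j for j, s in enumerate(gm1.snps["snp_id"])}
        snp_pos2 = {s: j for j, s in enumerate(gm2.snps["snp_id"])}
        for snp in top_snps:
            if snp not in snp_pos2:
                continue
            try:
                f1 = fit_hr(gm1.calls[:, snp_pos1[snp]], inputs1)
                f2 = fit_hr(gm2.calls[:, snp_pos2[snp]], inputs2)
                fc = combined_stage_fit(
                    carriers1,
                    gm1.calls[:, snp_pos1[snp]],
                    carriers2,
                    gm2.calls[:, snp_pos2[snp]],
                    incidence,
                )
                meta_hr, meta_ci = meta_fixed_effect(
                    float(f1.hr[0]),
                    (float(f1.ci_low[0]), float(f1.ci_high[0])),
                    float(f2.hr[0]),
                    (float(f2.ci_low[0]), float(f2.ci_high[0])),
                )
            except ValidationError as e:
                log.warning("fit failed for %s: %s", snp, e)
                continue
            rows.append(
                {
                    "snp": snp,
                    "hr_stage1": f1.hr[0],
                    "ci_stage1": f"{f1.ci_low[0]:.3f}-{f1.ci_high[0]:.3f}",
                    "hr_stage2": f2.hr[0],
                    "ci_stage2": f"{f2.ci_low[0]:.3f}-{f2.ci_high[0]:.3f}",
                    "hr_combined": fc.hr[0],
                    "ci_combined": f"{fc.ci_low[0]:.3f}-{fc.ci_high[0]:.3f}",
                    "hr_meta": meta_hr,
                    "ci_meta": f"{meta_ci[0]:.3f}-{meta_ci[1]:.3f}",
                }
            )
        fits = pd.DataFrame(rows)
        bundle["stage2_fits"] = fits
        fits.to_csv(out_dir / "fits_combined.tsv", sep="\t", index=False)

    if cfg.annotations and cfg.gene_sets:
        sets = cio.read_gene_sets(cfg.gene_sets)
        if not sets:
            log.warning("gene-set file is empty; GSEA stage skipped")
        else:
            ann = cio.read_annotations_bed(cfg.annotations)
            assign = map_snps_to_genes(
                gm1.snps, ann, up=cfg.gsea_up_kb * 1000, down=cfg.gsea_down_kb * 1000
            )
            snp_p = dict(zip(scan.results["snp"], scan.results["p"]))
            snp_p = {k: v for k, v in snp_p.items() if np.isfinite(v)}
            scores = gene_scores(assign, snp_p, annotations=ann)
            enrich = {
                name: gsea_p(
                    genes,
                    scores,
                    percentile=cfg.gsea_percentile,
                    n_random=cfg.gsea_n_random,
                    seed=np.random.default_rng(cfg.seed),
                )
                for name, genes in sets.items()
                if any(g in set(scores["gene"]) for g in genes)
            }
            bundle["gsea"] = enrich
            scores.to_csv(out_dir / "gene_scores.tsv", sep="\t", index=False)
            with open(out_dir / "gsea.json", "w") as fh:
                json.dump(enrich, fh, indent=1, default=str)

    if cfg.genetic_map:
        gmap = GeneticMap.read(cfg.genetic_map)
        segs = detect_segments(
            gm1.calls,
            gm1.sample_ids,
            gm1.snps,
            gmap,
            min_cm=cfg.ibd_min_cm,
            mode="genotype",
        )
        seg_df = pd.DataFrame(
            [
                {
                    "id1": s.id1,
                    "id2": s.id2,
                    "chrom": s.chrom,
                    "start_bp": s.start_bp,
                    "end_bp": s.end_bp,
                    "cm": s.length_cm,
                }
                for s in segs
            ]
        )
        bundle["ibd_segments"] = seg_df
        seg_df.to_csv(out_dir / "ibd_segments.tsv", sep="\t", index=False)

    with open(out_dir / "ledger.json", "w") as fh:
        json.dump(ledger, fh, indent=1)
    return bundle
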