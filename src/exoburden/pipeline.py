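"""End-to-end orchestration: QC -> PCA -> single-variant -> gene-based
-> ISUB, driven by one YAML-able configuration.

Stages communicate through files (PLINK sets and TSVs) so each is
independently runnable; a JSON manifest records input hashes,
parameters, seeds and row counts per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, burden, isub, pca, qc
from .io import (
    GenotypeStudy,
    attach_annotations,
    read_annotation_table,
    read_covariate_table,
    read_plink,
    write_plink,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    bfile: str
    out_dir: str
    annotation: str | None = None
    covariates_file: str | None = None
    # qc
    sample_missing_max: float = 0.05
    het_sd: float = 4.0
    pihat_max: float = 0.2
    prune_maf_min: float = 0.05
    prune_call_rate_min: float = 0.99
    prune_r2_max: float = 0.05
    prune_hwe_p_min: float = 1e-3
    variant_call_rate_min: float = 0.98
    hwe_controls_p_min: float = 1e-6
    diff_missing_p_min: float = 5e-3
    # pca
    n_pcs: int = 10
    outlier_sd: float = 10.0
    outlier_pcs: int = 4
    # association
    assoc_covariates: list = field(
        default_factory=lambda: ["PC1", "PC2", "PC3", "PC4", "PC5", "sex", "country"]
    )
    alpha: float = 0.05
    # gene-based
    gene_maf_max: float = 0.01
    gene_mac_min: int = 2
    permutations: int = 500_000
    p_trigger: float = 1e-3
    # isub
    isub_covariates: list = field(
        default_factory=lambda: ["PC1", "PC2", "PC3", "PC4", "PC5", "country"]
    )
    isub_ref_maf_max: float = 0.005
    balanced_cohorts: list | None = None
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        for name in ("bfile",):
            prefix = Path(getattr(self, name))
            for ext in (".bed", ".bim", ".fam"):
                f = prefix.with_suffix(ext)
                if not f.exists():
                    problems.append(f"missing input file: {f}")
        for name in ("annotation", "covariates_file"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                problems.append(f"missing input file: {val}")
        return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Validation failures are enumerated before any computation; each
    stage's outputs and row counts land in ``manifest.json``.
    """
    problems = config.validate()
    if problems:
        raise FileNotFoundError("; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "inputs": {},
        "stages": [],
    }
    prefix = Path(config.bfile)
    for ext in (".bed", ".bim", ".fam"):
        f = prefix.with_suffix(ext)
        manifest["inputs"][f.name] = _sha256(f)

    study = read_plink(config.bfile)
    if config.annotation:
        ann = read_annotation_table(config.annotation)
        cov = (
            read_covariate_table(config.covariates_file)
            if config.covariates_file
            else None
        )
        study = attach_annotations(study, ann, cov)

    # -- stage 1: QC -------------------------------------------------------
    pruned = qc.ld_prune(
        study,
        maf_min=config.prune_maf_min,
        call_rate_min=config.prune_call_rate_min,
        r2_max=config.prune_r2_max,
        hwe_p_min=config.prune_hwe_p_min,
    )
    study, sreport = qc.sample_qc(
        study,
        missing_rate_max=config.sample_missing_max,
        het_sd=config.het_sd,
        pihat_max=config.pihat_max,
        pruned_variants=pruned,
    )
    study, vreport = qc.variant_qc(
        study,
        call_rate_min=config.variant_call_rate_min,
        hwe_controls_p_min=config.hwe_controls_p_min,
        diff_missing_p_min=config.diff_missing_p_min,
    )
    report = pd.concat([sreport.to_frame(), vreport.to_frame()], ignore_index=True)
    report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    write_plink(study, out / "qc")
    manifest["stages"].append(
        {"stage": "qc", "n_samples": study.n_samples, "n_variants": study.n_variants,
         "outputs": ["qc_report.tsv", "qc.bed"]}
    )

    # -- stage 2: PCA ------------------------------------------------------
    pruned = qc.ld_prune(
        study,
        maf_min=config.prune_maf_min,
        call_rate_min=config.prune_call_rate_min,
        r2_max=config.prune_r2_max,
        hwe_p_min=config.prune_hwe_p_min,
    )
    if pruned.size >= 2:
        pcs = pca.compute_pcs(study, pruned, k=config.n_pcs)
        k = pcs.scores.shape[1]
        for c in range(k):
            study.samples[f"PC{c + 1}"] = pcs.scores[:, c]
        scores = pd.DataFrame(
            pcs.scores, columns=[f"PC{c + 1}" for c in range(k)]
        )
        scores.insert(0, "sample_id", study.samples["sample_id"])
        scores.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    else:
        logger.warning("pipeline: too few pruned SNPs for PCA; stage reduced")
        k = 0
    manifest["stages"].append(
        {"stage": "pca", "n_components": k, "n_pruned_snps": int(pruned.size),
         "outputs": ["pca_scores.tsv"] if k else []}
    )

    # -- stage 3: single-variant ------------------------------------------
    poly = qc.nonmonomorphic_filter(study)
    tested = study.take_variants(poly)
    covs = [c for c in config.assoc_covariates if c in tested.samples.columns]
    res = assoc.logistic_assoc(tested, covs)
    res.table.to_csv(out / "single_variant.tsv", sep="\t", index=False)
    pvals = res.pvalues()
    finite = pvals[np.isfinite(pvals)]
    lam = assoc.genomic_inflation(finite) if finite.size else np.nan
    thr = assoc.bonferroni_threshold(config.alpha, max(len(finite), 1))
    assoc.qq_table(finite).to_csv(out / "qq.tsv", sep="\t", index=False)
    manifest["stages"].append(
        {"stage": "single_variant", "n_tests": int(finite.size),
         "lambda_gc": None if np.isnan(lam) else float(lam),
         "bonferroni_threshold": thr,
         "outputs": ["single_variant.tsv", "qq.tsv"]}
    )

    # -- stage 4: gene-based ----------------------------------------------
    if "gene" in study.variants.columns and study.variants["gene"].notna().any():
        scan = burden.gene_burden_scan(
            study, covs,
            maf_max=config.gene_maf_max, mac_min=config.gene_mac_min,
            B=config.permutations, p_trigger=config.p_trigger,
            seed=config.seed,
        )
        scan.table.to_csv(out / "gene_burden.tsv", sep="\t", index=False)
        n_genes = len(scan.table)
    else:
        logger.warning("pipeline: no gene annotations; gene stage skipped")
        n_genes = 0
    manifest["stages"].append(
        {"stage": "gene_burden", "n_genes_tested": n_genes,
         "outputs": ["gene_burden.tsv"] if n_genes else []}
    )

    # -- stage 5: ISUB -----------------------------------------------------
    if "functional_class" in study.variants.columns:
        icovs = [c for c in config.isub_covariates if c in study.samples.columns]
        results = isub.run_isub(study, icovs, ref_maf_max=config.isub_ref_maf_max)
        rows = []
        for name, r in results.items():
            for _, g in r.group_summary.iterrows():
                rows.append({"variant_class": name, "cohorts": "all",
                             "comparison_p": r.comparison_p, **g.to_dict()})
        if config.balanced_cohorts:
            bal = isub.balanced_subset_analysis(
                study, tuple(config.balanced_cohorts), icovs,
                ref_maf_max=config.isub_ref_maf_max,
            )
            for name, r in bal.items():
                for _, g in r.group_summary.iterrows():
                    rows.append({"variant_class": name,
                                 "cohorts": ",".join(config.balanced_cohorts),
                                 "comparison_p": r.comparison_p, **g.to_dict()})
        pd.DataFrame(rows).to_csv(out / "isub_summary.tsv", sep="\t", index=False)
        n_isub = len(rows)
    else:
        logger.warning("pipeline: no functional annotations; ISUB stage skipped")
        n_isub = 0
    manifest["stages"].append(
        {"stage": "isub", "n_summary_rows": n_isub,
         "outputs": ["isub_summary.tsv"] if n_isub else []}
    )

    # -- stage 6: report ---------------------------------------------------
    manifest["stages"].append({"stage": "report", "outputs": ["manifest.json"]})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
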