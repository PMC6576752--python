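"""End-to-end orchestration: regions -> pairing -> filtering -> fractions
-> gene-level aeQTL -> txSNP-level aeQTL -> eQTL -> FDR -> bias QC.

The CLI is a thin shell over :func:`run_analysis`; tests and the
acceptance script call it directly on in-memory tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import bias as bias_qc
from .core import build_fraction_records
from .io import RunConfig
from .models import (annotate_fdr, compute_pcs, covariate_frame, fit_aeqtl,
                     fit_eqtl, fit_txsnp_aeqtl)
from .regions import build_regions, pair_risk_snps, pairs_table
from .types import AnnotationSet, GenotypeTable, QtlResult


@dataclass
class AnalysisResult:
    """Everything one pipeline run produces."""

    regions: list
    pairs: list
    gene_results: list[QtlResult] = field(default_factory=list)
    txsnp_results: list[QtlResult] = field(default_factory=list)
    eqtl_results: list[QtlResult] = field(default_factory=list)
    bias_checks: list[QtlResult] = field(default_factory=list)
    fraction_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    funnels: dict[str, dict] = field(default_factory=dict)
    bias_summary: Optional[bias_qc.BiasSummary] = None
    gene_fdr_cutoff: float = 0.0
    txsnp_fdr_cutoff: float = 0.0
    manifest: dict = field(default_factory=dict)


def _dosage_vector(genotypes: GenotypeTable, samples: list[str],
                   snp_id: str, allele: str) -> np.ndarray:
    out = np.full(len(samples), np.nan)
    for i, s in enumerate(samples):
        gt = genotypes.genotype(s, snp_id)
        if gt is not None:
            out[i] = (gt.allele1 == allele) + (gt.allele2 == allele)
    return out


def standard_covariates(
    genotypes: GenotypeTable,
    expression: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    cfg: RunConfig,
) -> pd.DataFrame:
    """The default covariate design: age, sex, top genotype PCs and top
    expression PCs, computed once on the full cohort (the same design
    enters every aeQTL and eQTL fit)."""
    samples = genotypes.samples
    geno_mat = np.full((len(samples), len(genotypes.snps)), np.nan)
    for j, sid in enumerate(genotypes.snps.index):
        alt = genotypes.snps.iloc[j]["alt"]
        col_a1 = genotypes.allele1[:, j]
        col_a2 = genotypes.allele2[:, j]
        for i in range(len(samples)):
            if col_a1[i] is not None:
                geno_mat[i, j] = (col_a1[i] == alt) + (col_a2[i] == alt)
    geno_pcs = compute_pcs(geno_mat, cfg.k_geno_pcs)
    expr_mat = expression.reindex(samples).to_numpy(dtype=float)
    if cfg.eqtl_transform == "log2":
        expr_mat = np.log2(expr_mat + 1.0)
    expr_pcs = compute_pcs(expr_mat, cfg.k_expr_pcs)
    base = None
    if covariates is not None:
        keep = [c for c in ("age", "sex") if c in covariates.columns]
        base = covariates[keep]
    cov = covariate_frame(samples, base, geno_pcs, expr_pcs)
    # zero-variance PCs (k beyond rank) carry no information; drop them
    return cov.loc[:, cov.std(ddof=0) > 1e-12]


def run_analysis(
    genotypes: GenotypeTable,
    counts: pd.DataFrame,
    annotation: AnnotationSet,
    risk_snps: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    cfg: Optional[RunConfig] = None,
    use_covariates: bool = True,
) -> AnalysisResult:
    """Run the full phase-aware QTL analysis on validated tables."""
    cfg = cfg or RunConfig()
    fcfg = cfg.filter_config()
    regions = build_regions(annotation, counts)
    pairs = pair_risk_snps(regions, risk_snps, cfg.window)
    by_region = {r.region_id: r for r in regions}

    cov = (standard_covariates(genotypes, expression, covariates, cfg)
           if use_covariates else None)

    out = AnalysisResult(regions=regions, pairs=pairs)
    out.bias_summary = None
    try:
        out.bias_summary = bias_qc.ref_fraction_summary(counts, genotypes)
    except ValueError:
        pass

    n_testable = 0
    for pair in pairs:
        region = by_region[pair.region_id]
        pid = f"{pair.risk_snp_id}|{pair.region_id}"
        risk_rec = risk_snps.loc[pair.risk_snp_id]
        snp_meta = genotypes.snps.loc[pair.risk_snp_id]
        designated = snp_meta["ref"]  # internal ref-orientation coding
        risk_is_designated = risk_rec["risk_allele"] == designated

        records, funnel = build_fraction_records(
            counts, genotypes, region, pair.risk_snp_id, designated, fcfg,
            summary=cfg.region_summary)
        out.fraction_tables[pid] = records
        out.funnels[pid] = funnel.as_dict()

        meta = {
            "snp_id": pair.risk_snp_id, "region_id": pair.region_id,
            "distance": pair.distance, "distance_rank": pair.distance_rank,
            "ref": snp_meta["ref"], "alt": snp_meta["alt"],
        }

        if funnel.testable:
            n_testable += 1
            extras = dict(meta)
            extras["n_txsnps"] = int(records["n_txsnps"].sum())
            extras["max_reads"] = int(records["total_reads"].max())
            r = fit_aeqtl(records, _align_cov(cov, records), pair_id=pid,
                          coding=cfg.group_coding,
                          risk_is_designated=risk_is_designated, **extras)
            out.gene_results.append(r)

            # mapping-bias diagnostic on the same samples, phase-free
            rec_b = bias_qc.add_dosage(records, genotypes, pair.risk_snp_id,
                                       risk_rec["risk_allele"])
            out.bias_checks.append(bias_qc.group_bias_check(rec_b, pid))

            # txSNP-level family
            tx_records, _ = build_fraction_records(
                counts, genotypes, region, pair.risk_snp_id, designated,
                fcfg, per_txsnp=True)
            out.txsnp_results.extend(fit_txsnp_aeqtl(
                tx_records, _align_cov(cov, tx_records), pair_id=pid,
                min_group_n=fcfg.min_group_n, min_groups=fcfg.min_groups,
                risk_is_designated=risk_is_designated))

        # comparison eQTL per member gene on all dosage-called samples
        dosage = _dosage_vector(genotypes, genotypes.samples,
                                pair.risk_snp_id, risk_rec["risk_allele"])
        ok = ~np.isnan(dosage)
        for gid in region.gene_ids:
            if gid not in expression.columns:
                continue
            y = expression[gid].reindex(genotypes.samples).to_numpy(dtype=float)
            ok_g = ok & ~np.isnan(y)
            if ok_g.sum() < 4 or len(np.unique(dosage[ok_g])) < 2:
                continue
            if cfg.eqtl_transform == "log2":
                y = np.log2(y + 1.0)
            cov_e = cov.loc[np.asarray(genotypes.samples)[ok_g]] if cov is not None else None
            out.eqtl_results.append(fit_eqtl(
                y[ok_g], dosage[ok_g], cov_e, pair_id=f"{pid}|{gid}", **meta))

    out.gene_fdr_cutoff = annotate_fdr(out.gene_results, cfg.alpha)
    out.txsnp_fdr_cutoff = annotate_fdr(out.txsnp_results, cfg.alpha)
    annotate_fdr(out.eqtl_results, cfg.alpha)

    out.manifest = {
        "n_samples": len(genotypes.samples),
        "n_snps": int(len(genotypes.snps)),
        "n_genes": int(len(annotation.genes)),
        "n_regions": len(regions),
        "n_risk_snps": int(len(risk_snps)),
        "n_pairs": len(pairs),
        "n_testable_pairs": n_testable,
        "n_gene_results": len(out.gene_results),
        "n_txsnp_results": len(out.txsnp_results),
        "n_eqtl_results": len(out.eqtl_results),
        "n_gene_significant": sum(
            r.extras.get("significant", False) for r in out.gene_results),
        "n_txsnp_significant": sum(
            r.extras.get("significant", False) for r in out.txsnp_results),
        "gene_fdr_cutoff": out.gene_fdr_cutoff,
        "txsnp_fdr_cutoff": out.txsnp_fdr_cutoff,
        "funnel_totals": {
            k: int(sum(f[k] for f in out.funnels.values()))
            for k in ("n_candidates", "n_fail_reads", "n_fail_minor", "n_pass")
        },
        "global_ref_fraction": (
            None if out.bias_summary is None
            else out.bias_summary.global_mean),
    }
    return out


def _align_cov(cov: Optional[pd.DataFrame],
               records: pd.DataFrame) -> Optional[pd.DataFrame]:
    if cov is None:
        return None
    return cov.reindex(records["sample"])
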