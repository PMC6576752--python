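"""Calibration and power evaluation of the aeQTL method on simulated
cohorts: null FDR control, p-value uniformity, effect recovery, flip
symmetry, mapping-bias recovery and flagging, and the power comparison
against the phase-free variance test.

These routines drive both the statistical test suite and the reproduction
script; each takes an explicit seed and runs the full count -> filter ->
fraction -> regression path rather than shortcutting to fractions.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import scipy.stats

from .bias import add_dosage, group_bias_check, ref_fraction_summary
from .core import build_fraction_records
from .models import AllelicVarianceTest, bh_fdr, fit_aeqtl
from .regions import build_regions
from .simulate import SimConfig, simulate_cohort, simulate_null_batch
from .types import FilterConfig


def _gene_fits(cohort, designated_by_gene: str = "risk", cfg: FilterConfig | None = None,
               flip_risk: bool = False):
    """Fit the gene-level aeQTL for every simulated gene in a cohort.

    ``designated_by_gene``: "risk" codes groups with the risk (alt) allele
    on parent 1 -> group 0; "ref" uses the reference allele.  ``flip_risk``
    relabels the parent haplotypes at each risk SNP before coding, the
    transformation under which the slope must exactly negate.
    Yields (gene_truth, records, QtlResult or None-if-untestable).
    """
    fcfg = cfg or FilterConfig()
    regions = {r.gene_ids[0]: r for r in
               build_regions(cohort.annotation, cohort.counts)}
    genotypes = cohort.genotypes
    if flip_risk:
        genotypes = genotypes.flipped(
            snps=[g["risk_snp_id"] for g in cohort.truth["genes"]])
    # pre-split the count table once; scanning it per gene is quadratic
    snp_to_region = {t: r.region_id for r in regions.values()
                     for t in r.txsnp_ids}
    by_region = dict(tuple(
        cohort.counts.groupby(cohort.counts["snp_id"].map(snp_to_region))))
    for g in cohort.truth["genes"]:
        designated = ("G" if designated_by_gene == "risk" else "A")
        region = regions[g["gene_id"]]
        sub = by_region.get(region.region_id, cohort.counts.iloc[:0])
        records, funnel = build_fraction_records(
            sub, genotypes, region, g["risk_snp_id"], designated, fcfg)
        fit = None
        if funnel.testable:
            fit = fit_aeqtl(records, pair_id=g["gene_id"])
        yield g, records, fit


def null_calibration(n_cohorts: int, genes_per_cohort: int, seed: int,
                     base: SimConfig | None = None, alpha: float = 0.05) -> dict:
    """Simulate null cohorts (pi = 0.5) and measure BH discovery rate and
    p-value uniformity of the gene-level aeQTL."""
    base = base or SimConfig()
    sig_fracs, pooled_p = [], []
    for c in range(n_cohorts):
        cohort = simulate_null_batch(replace(base, seed=seed + c),
                                     genes_per_cohort)
        pvals = [f.pvalue for _, _, f in _gene_fits(cohort) if f is not None]
        if pvals:
            _, rej, _ = bh_fdr(pvals, alpha)
            sig_fracs.append(rej.mean())
            pooled_p.extend(pvals)
    ks = scipy.stats.kstest(pooled_p, "uniform")
    return {
        "mean_significant_fraction": float(np.mean(sig_fracs)),
        "n_tests": len(pooled_p),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def effect_recovery(n_replicates: int, seed: int,
                    base: SimConfig | None = None) -> dict:
    """With risk-allele group coding, group-0 minus group-2 mean fraction
    estimates 2*pi - 1; also measures the slope-sign agreement with phase
    (a positive share pi > 0.5 must yield a negative per-step slope)."""
    base = base or SimConfig()
    gaps, sign_ok = [], []
    for r in range(n_replicates):
        cohort = simulate_cohort(replace(base, seed=seed + r, n_genes=1))
        for g, rec, fit in _gene_fits(cohort, designated_by_gene="risk"):
            if fit is None:
                continue
            m = rec.groupby("group")["fraction_p1"].mean()
            if 0 in m.index and 2 in m.index:
                gaps.append(m[0] - m[2])
            # group 0 has the risk allele on parent 1 -> high fraction;
            # fraction falls with the group index when pi > 0.5
            sign_ok.append(fit.slope < 0 if base.pi > 0.5 else fit.slope > 0)
    gaps = np.asarray(gaps)
    return {
        "mean_gap": float(gaps.mean()),
        "expected_gap": 2 * base.pi - 1,
        "mc_se": float(gaps.std(ddof=1) / np.sqrt(len(gaps))),
        "sign_match_rate": float(np.mean(sign_ok)),
        "n": len(gaps),
    }


def flip_symmetry(n_genes: int, seed: int,
                  base: SimConfig | None = None) -> dict:
    """Exact phase-relabeling symmetries of the aeQTL fit.

    Relabeling the parent haplotypes at the risk SNP (g -> 2-g, fractions
    untouched) must negate the slope and leave the p-value unchanged;
    relabeling every SNP (g -> 2-g and f -> 1-f jointly) must leave both
    unchanged.  Returns the maximal discrepancies over a simulated batch.
    """
    base = base or SimConfig()
    cohort = simulate_cohort(replace(base, seed=seed, n_genes=n_genes))
    orig = {g["gene_id"]: f for g, _, f in _gene_fits(cohort) if f is not None}
    flip = {g["gene_id"]: f
            for g, _, f in _gene_fits(cohort, flip_risk=True) if f is not None}

    full = simulate_cohort(replace(base, seed=seed, n_genes=n_genes))
    full.genotypes = full.genotypes.flipped()  # every SNP, every sample
    both = {g["gene_id"]: f for g, _, f in _gene_fits(full) if f is not None}

    ids = sorted(set(orig) & set(flip) & set(both))
    return {
        "n_genes": len(ids),
        "max_slope_negation_err": max(
            abs(orig[i].slope + flip[i].slope) for i in ids),
        "max_p_diff_riskflip": max(
            abs(orig[i].pvalue - flip[i].pvalue) for i in ids),
        "max_slope_diff_fullflip": max(
            abs(orig[i].slope - both[i].slope) for i in ids),
        "max_p_diff_fullflip": max(
            abs(orig[i].pvalue - both[i].pvalue) for i in ids),
    }


def bias_recovery(seed: int, bias: float = 0.015, n_samples: int = 500,
                  n_txsnps: int = 100, depth: float = 100.0) -> dict:
    """Global ref-allele fraction with and without an injected mapping
    bias; the biased mean must recover 0.5 + bias."""
    out = {}
    for label, b in (("biased", bias), ("unbiased", 0.0)):
        cfg = SimConfig(n_samples=n_samples, n_genes=max(1, n_txsnps // 4),
                        txsnps_per_gene=4, pi=0.5, depth_mean=depth,
                        bias_ref=b, seed=seed)
        cohort = simulate_cohort(cfg)
        s = ref_fraction_summary(cohort.counts, cohort.genotypes, label)
        per = s.per_txsnp["mean_ref_fraction"]
        out[label] = {
            "global_mean": s.global_mean,
            "mc_se": float(per.std(ddof=1) / np.sqrt(len(per))),
            "n_txsnps": int(len(per)),
        }
    out["expected_biased_mean"] = 0.5 + bias
    return out


def bias_flag_rates(n_seeds: int, seed: int, coeff: float = 0.05,
                    base: SimConfig | None = None) -> dict:
    """Sensitivity and false-flag rate of the genotype-group bias check.

    Adversarial cohorts couple the ref-probability shift to risk-allele
    dosage (coeff per copy); null cohorts carry a genotype-independent
    global bias.  The default adversarial strength, 0.05 per copy, matches
    the magnitude of the weakest allele-fraction effects the aeQTL model
    reports as discoveries — i.e. a bias large enough to masquerade as a
    real signal, which is exactly what the diagnostic must catch.
    """
    base = base or SimConfig(pi=0.5)
    flags_adv, flags_null = [], []
    for s in range(n_seeds):
        for mode, sink in (("adv", flags_adv), ("null", flags_null)):
            cfg = replace(
                base, seed=seed + 7919 * s + (0 if mode == "adv" else 1),
                pi=0.5,
                bias_ref=0.0 if mode == "adv" else 0.015,
                bias_genotype_coeff=coeff if mode == "adv" else 0.0)
            cohort = simulate_cohort(cfg)
            for g, rec, _ in _gene_fits(cohort):
                rec = add_dosage(rec, cohort.genotypes, g["risk_snp_id"], "G")
                res = group_bias_check(rec, g["gene_id"])
                sink.append(res.extras["flagged"])
    return {
        "sensitivity": float(np.mean(flags_adv)),
        "false_flag_rate": float(np.mean(flags_null)),
        "n_each": len(flags_adv),
    }


def power_comparison(n_replicates: int, seed: int,
                     base: SimConfig | None = None,
                     alpha: float = 0.05) -> dict:
    """Power of the phase-coded aeQTL vs the phase-free variance test on
    identical simulated data."""
    base = base or SimConfig()
    ae_hits, var_hits = [], []
    for r in range(n_replicates):
        cohort = simulate_cohort(replace(base, seed=seed + r, n_genes=1))
        for _, rec, fit in _gene_fits(cohort):
            if fit is None:
                continue
            ae_hits.append(fit.pvalue < alpha)
            vt = AllelicVarianceTest().fit(
                rec["fraction_p1"], rec["group"] != 1)
            var_hits.append(vt.pvalue_ < alpha)
    return {
        "aeqtl_power": float(np.mean(ae_hits)),
        "variance_power": float(np.mean(var_hits)),
        "power_gap": float(np.mean(ae_hits) - np.mean(var_hits)),
        "n": len(ae_hits),
    }


def pair_window_agreement(n_layouts: int, seed: int,
                          window: int = 200_000) -> dict:
    """Randomized cross-check of risk-SNP pairing against a brute-force
    per-gene distance scan, including exact window-boundary layouts."""
    from .regions import pair_risk_snps, span_distance
    from .types import AnnotationSet

    rng = np.random.default_rng(seed)
    n_mismatch = 0
    n_pairs = 0
    for lay in range(n_layouts):
        n_genes = rng.integers(1, 6)
        n_snps = rng.integers(1, 4)
        starts = np.sort(rng.integers(0, 2_000_000, n_genes))
        lengths = rng.integers(1_000, 300_000, n_genes)
        genes = pd.DataFrame({
            "gene_id": [f"g{lay}_{i}" for i in range(n_genes)],
            "chrom": "chr1", "strand": "+",
            "start": starts, "end": starts + lengths,
        }).set_index("gene_id")
        exons = {g: [(int(r["start"]), int(r["end"]))]
                 for g, r in genes.iterrows()}
        ann = AnnotationSet(genes, exons)
        counts = pd.DataFrame(columns=["sample", "snp_id", "chrom", "pos",
                                       "ref_count", "alt_count"])
        regions = build_regions(ann, counts)

        pos = rng.integers(0, 2_300_000, n_snps)
        if lay % 5 == 0 and n_genes:
            # force exact boundary layouts around the first gene
            pos[0] = genes.iloc[0]["start"] - window
            if n_snps > 1:
                pos[1] = genes.iloc[0]["start"] - window - 2
        risk = pd.DataFrame({
            "snp_id": [f"rs{lay}_{i}" for i in range(n_snps)],
            "chrom": "chr1", "pos": pos + 1, "risk_allele": "G",
        }).set_index("snp_id")

        got = {(p.risk_snp_id, p.region_id, p.distance, p.distance_rank)
               for p in pair_risk_snps(regions, risk, window)}

        # brute force: per-gene scan, genes then mapped to their region
        gene_region = {g: r.region_id for r in regions for g in r.gene_ids}
        want = set()
        for sid, srec in risk.iterrows():
            p0 = srec["pos"] - 1
            dists = {}
            for g, grow in genes.iterrows():
                d = span_distance(p0, (grow["start"], grow["end"]))
                rid = gene_region[g]
                if rid not in dists or abs(d) < abs(dists[rid]):
                    dists[rid] = d
            inside = sorted(
                ((abs(d), rid, d) for rid, d in dists.items()
                 if abs(d) <= window))
            for rank, (_, rid, d) in enumerate(inside, start=1):
                want.add((sid, rid, d, rank))
        n_pairs += len(want)
        if got != want:
            n_mismatch += 1
    return {"n_layouts": n_layouts, "n_pairs_checked": n_pairs,
            "n_mismatched_layouts": n_mismatch}
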