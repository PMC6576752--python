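"""Phase-aware allele-fraction computation and the QC filter cascade.

The central quantity is fraction_P1: for one sample and one gene's
txSNP-region, the mean over usable heterozygous txSNPs of
(parent-1 reads) / (parent-1 + parent-2 reads).  A sample's risk-SNP
genotype is coded 0/1/2 by phase: designated allele on parent-1, homozygous,
designated allele on parent-2.  Regression of fraction_P1 on this group is
the aeQTL test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import FilterConfig, GenotypeTable, PhasedGenotype, TxSnpRegion


class PhaseError(ValueError):
    """Phase-dependent operation applied to an unphased or homozygous call."""


def classify_het(gt: PhasedGenotype) -> bool:
    """True iff the two alleles differ.  Phase is irrelevant here, but an
    unphased heterozygote is unusable for every phase-dependent step."""
    return gt.allele1 != gt.allele2


def filter_txsnp_sample(ref_count: int, alt_count: int, cfg: FilterConfig) -> bool:
    """Per-sample, per-txSNP read filter.

    Passes iff the less-covered allele has >= ``min_reads_per_allele`` reads
    AND contributes >= ``min_minor_fraction`` of the site's expression
    (guards against sequencing errors mimicking imbalance).  Zero total
    coverage fails.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("negative read count")
    total = ref_count + alt_count
    if total == 0:
        return False
    minor = min(ref_count, alt_count)
    return minor >= cfg.min_reads_per_allele and minor / total >= cfg.min_minor_fraction


def phase_orient(
    ref_count: int, alt_count: int, gt: PhasedGenotype, ref: str, alt: str
) -> tuple[int, int]:
    """Map (ref, alt) read counts to (parent-1, parent-2) counts via phase."""
    if not gt.heterozygous:
        raise PhaseError("homozygous genotype: parent-1 fraction is uninformative")
    if not gt.phased:
        raise PhaseError("unphased heterozygote: parent-1 is undefined")
    if gt.allele1 == ref and gt.allele2 == alt:
        return ref_count, alt_count
    if gt.allele1 == alt and gt.allele2 == ref:
        return alt_count, ref_count
    raise ValueError(f"genotype alleles {gt.allele1}/{gt.allele2} not ref/alt {ref}/{alt}")


def risk_group(gt: PhasedGenotype, designated_allele: str) -> int:
    """Three-level phase coding of the risk-SNP genotype.

    0: heterozygous, designated allele on parent-1;
    1: homozygous (either allele);
    2: heterozygous, designated allele on parent-2.
    """
    if not gt.heterozygous:
        return 1
    if not gt.phased:
        raise PhaseError("unphased heterozygous risk-SNP: group is undefined")
    if gt.allele1 == designated_allele:
        return 0
    if gt.allele2 == designated_allele:
        return 2
    raise ValueError(
        f"designated allele {designated_allele!r} absent from genotype "
        f"{gt.allele1}/{gt.allele2}"
    )


def summarize_region(
    p1_counts: np.ndarray, p2_counts: np.ndarray, method: str = "mean"
) -> tuple[float, int, int]:
    """Collapse one sample's usable txSNPs to a single fraction_P1.

    ``mean``: unweighted mean of per-txSNP fractions (the default — each
    heterozygous txSNP is one observation of the same haplotype ratio).
    ``pooled``: sum counts first (weights txSNPs by depth); offered for
    sensitivity analysis.
    Returns (fraction_P1, n_txsnps_used, total_reads).
    """
    p1 = np.asarray(p1_counts, dtype=float)
    p2 = np.asarray(p2_counts, dtype=float)
    if p1.size == 0:
        raise ValueError("no usable txSNPs to summarize")
    if method == "mean":
        frac = float(np.mean(p1 / (p1 + p2)))
    elif method == "pooled":
        frac = float(p1.sum() / (p1.sum() + p2.sum()))
    else:
        raise ValueError(f"unknown summary method {method!r}")
    return frac, int(p1.size), int(p1.sum() + p2.sum())


@dataclass
class FilterFunnel:
    """Per-pair accounting of where candidate records were lost.

    A candidate is a (sample, txSNP) with the sample heterozygous at the
    txSNP.  A record can fail both read filters; both reasons are counted.
    """

    n_candidates: int = 0
    n_unphased_txsnp: int = 0
    n_fail_reads: int = 0
    n_fail_minor: int = 0
    n_pass: int = 0
    n_samples_no_risk_gt: int = 0
    n_samples_unphased_risk: int = 0
    n_usable_samples: int = 0
    group_n: tuple[int, int, int] = (0, 0, 0)
    testable: bool = False

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["group_n"] = list(self.group_n)
        return d


def group_counts(groups) -> tuple[int, int, int]:
    g = np.asarray(groups, dtype=int)
    return tuple(int((g == k).sum()) for k in (0, 1, 2))


def testable(groups, cfg: FilterConfig) -> bool:
    """True iff >= ``min_groups`` genotype groups each have >=
    ``min_group_n`` usable individuals."""
    gn = group_counts(groups)
    return sum(n >= cfg.min_group_n for n in gn) >= cfg.min_groups


def build_fraction_records(
    counts: pd.DataFrame,
    genotypes: GenotypeTable,
    region: TxSnpRegion,
    risk_snp_id: str,
    designated_allele: str,
    cfg: FilterConfig,
    summary: str = "mean",
    per_txsnp: bool = False,
) -> tuple[pd.DataFrame, FilterFunnel]:
    """Assemble the per-sample fraction table for one (risk-SNP, region) pair.

    Returns a long DataFrame with columns
    sample, region_id, txsnp_id (per-txSNP mode only), fraction_p1,
    fraction_ref, n_txsnps, total_reads, group
    plus a :class:`FilterFunnel` recording every filter loss.
    ``fraction_ref`` is the reference-allele-oriented analogue of
    fraction_p1 used by the mapping-bias diagnostic.
    """
    funnel = FilterFunnel()
    cols = ["sample", "region_id"] + (["txsnp_id"] if per_txsnp else []) + [
        "fraction_p1", "fraction_ref", "n_txsnps", "total_reads", "group"]
    sub = counts[counts["snp_id"].isin(region.txsnp_ids)]
    if sub.empty:
        return pd.DataFrame(columns=cols), funnel

    # vectorized gather of genotype calls for the (sample, txSNP) rows
    si = sub["sample"].map(genotypes._sample_idx).to_numpy()
    sj = sub["snp_id"].map(genotypes._snp_idx).to_numpy()
    a1 = genotypes.allele1[si, sj]
    a2 = genotypes.allele2[si, sj]
    ph = genotypes.phased[si, sj]
    called = np.array([x is not None for x in a1])
    het = called & (a1 != a2)
    funnel.n_candidates = int(het.sum())
    funnel.n_unphased_txsnp = int((het & ~ph).sum())
    usable = het & ph

    rc = sub["ref_count"].to_numpy(dtype=float)
    ac = sub["alt_count"].to_numpy(dtype=float)
    total = rc + ac
    minor = np.minimum(rc, ac)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(total > 0, minor / np.maximum(total, 1), 0.0)
    fail_reads = usable & (minor < cfg.min_reads_per_allele)
    fail_minor = usable & ((total == 0) | (minor_frac < cfg.min_minor_fraction))
    funnel.n_fail_reads = int(fail_reads.sum())
    funnel.n_fail_minor = int(fail_minor.sum())
    keep = usable & ~fail_reads & ~fail_minor
    funnel.n_pass = int(keep.sum())

    snp_meta = genotypes.snps
    ref_allele = snp_meta["ref"].to_numpy(dtype=object)[sj]
    p1_is_ref = a1 == ref_allele
    p1c = np.where(p1_is_ref, rc, ac)
    p2c = np.where(p1_is_ref, ac, rc)

    used = sub.loc[keep, ["sample", "snp_id"]].copy()
    used["p1"] = p1c[keep]
    used["p2"] = p2c[keep]
    used["rc"] = rc[keep]
    used["ac"] = ac[keep]

    # risk-SNP group per sample with >=1 usable txSNP
    sample_group: dict[str, int] = {}
    for sample in sorted(used["sample"].unique()):
        gt_risk = genotypes.genotype(sample, risk_snp_id)
        if gt_risk is None:
            funnel.n_samples_no_risk_gt += 1
            continue
        try:
            sample_group[sample] = risk_group(gt_risk, designated_allele)
        except PhaseError:
            funnel.n_samples_unphased_risk += 1
    funnel.n_usable_samples = len(sample_group)

    used = used[used["sample"].isin(sample_group)]
    if per_txsnp:
        used = used.sort_values(["sample", "snp_id"])
        records = pd.DataFrame({
            "sample": used["sample"].to_numpy(),
            "region_id": region.region_id,
            "txsnp_id": used["snp_id"].to_numpy(),
            "fraction_p1": (used["p1"] / (used["p1"] + used["p2"])).to_numpy(),
            "fraction_ref": (used["rc"] / (used["rc"] + used["ac"])).to_numpy(),
            "n_txsnps": 1,
            "total_reads": (used["p1"] + used["p2"]).to_numpy().astype(int),
            "group": used["sample"].map(sample_group).to_numpy(),
        }, columns=cols)
    else:
        used = used.assign(
            f_p1=used["p1"] / (used["p1"] + used["p2"]),
            f_ref=used["rc"] / (used["rc"] + used["ac"]),
        )
        g = used.groupby("sample", sort=True)
        if summary == "mean":
            frac = g["f_p1"].mean()
            ref_frac = g["f_ref"].mean()
        elif summary == "pooled":
            frac = g["p1"].sum() / (g["p1"].sum() + g["p2"].sum())
            ref_frac = g["rc"].sum() / (g["rc"].sum() + g["ac"].sum())
        else:
            raise ValueError(f"unknown summary method {summary!r}")
        agg = pd.DataFrame({
            "fraction_p1": frac,
            "fraction_ref": ref_frac,
            "n_txsnps": g.size(),
            "total_reads": (g["p1"].sum() + g["p2"].sum()).astype(int),
        }).reset_index()
        agg["region_id"] = region.region_id
        agg["group"] = agg["sample"].map(sample_group)
        records = agg[cols].copy()

    if records.empty:
        records = pd.DataFrame(columns=cols)
    if not per_txsnp:
        funnel.group_n = group_counts(records["group"]) if len(records) else (0, 0, 0)
        funnel.testable = testable(records["group"], cfg) if len(records) else False
    return records, funnel
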