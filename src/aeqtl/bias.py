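"""Mapping-bias summaries and per-aeQTL model diagnostics.

Alignment favors reads carrying the reference base, so the cohort-wide
reference-allele fraction at heterozygous sites drifts above 0.5; the
magnitude of that drift (and its reduction after N-masked realignment)
is the headline QC number.  A per-pair regression of the ref-allele
fraction on the unphased risk-allele dosage flags aeQTLs that could be
bias artifacts: genuine phase effects cancel in ref orientation, while a
genotype-correlated mapping bias does not.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .types import GenotypeTable, QtlResult


@dataclass
class BiasSummary:
    """Reference-allele fraction over heterozygous sample x txSNP records."""

    label: str
    per_txsnp: pd.DataFrame  # index txsnp_id; columns mean_ref_fraction, n_het
    global_mean: float
    global_sd: float

    @property
    def deviation_from_half(self) -> float:
        return self.global_mean - 0.5


def ref_fraction_summary(
    counts: pd.DataFrame, genotypes: GenotypeTable, label: str = ""
) -> BiasSummary:
    """Cohort-wide reference-allele fraction at heterozygous txSNPs.

    Per heterozygous (sample, txSNP) with >=1 read: ref/(ref+alt); averaged
    per txSNP, then summarized as mean +/- SD over txSNPs with at least one
    informative sample.
    """
    si = counts["sample"].map(genotypes._sample_idx).to_numpy()
    sj = counts["snp_id"].map(genotypes._snp_idx).to_numpy()
    a1 = genotypes.allele1[si, sj]
    a2 = genotypes.allele2[si, sj]
    het = np.array([x is not None for x in a1]) & (a1 != a2)
    total = (counts["ref_count"] + counts["alt_count"]).to_numpy(dtype=float)
    use = het & (total > 0)
    if not use.any():
        raise ValueError("no informative sites: no heterozygous covered txSNPs")
    frac = counts.loc[use, "ref_count"].to_numpy(dtype=float) / total[use]
    per = (
        pd.DataFrame({"txsnp_id": counts.loc[use, "snp_id"], "frac": frac})
        .groupby("txsnp_id")["frac"]
        .agg(mean_ref_fraction="mean", n_het="size")
    )
    return BiasSummary(
        label=label,
        per_txsnp=per,
        global_mean=float(per["mean_ref_fraction"].mean()),
        global_sd=float(per["mean_ref_fraction"].std(ddof=1))
        if len(per) > 1 else 0.0,
    )


def compare_count_sets(
    a: pd.DataFrame, b: pd.DataFrame, genotypes: GenotypeTable,
    labels: tuple[str, str] = ("a", "b"),
) -> dict:
    """Paired per-txSNP comparison of ref-allele fractions in two count
    sets (e.g. unmasked vs N-masked alignments of the same reads).

    The sample/txSNP universe is intersected; returns the two global means,
    the per-txSNP paired differences and a paired-test p-value (Wilcoxon
    signed-rank; p = 1.0 for identical tables).
    """
    key = ["sample", "snp_id"]
    common = pd.merge(a[key], b[key], on=key)
    a_c = a.merge(common, on=key)
    b_c = b.merge(common, on=key)
    sum_a = ref_fraction_summary(a_c, genotypes, labels[0])
    sum_b = ref_fraction_summary(b_c, genotypes, labels[1])
    joined = sum_a.per_txsnp.join(
        sum_b.per_txsnp, lsuffix="_a", rsuffix="_b", how="inner")
    diff = (joined["mean_ref_fraction_a"] - joined["mean_ref_fraction_b"]).to_numpy()
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        _, p = scipy.stats.wilcoxon(diff)
        p = float(p)
    return {
        "summary_a": sum_a,
        "summary_b": sum_b,
        "per_txsnp_difference": pd.Series(diff, index=joined.index),
        "mean_difference": float(diff.mean()),
        "paired_pvalue": p,
        "n_txsnps": int(len(diff)),
        "n_records_intersected": int(len(common)),
    }


def group_bias_check(records: pd.DataFrame, pair_id: str = "") -> QtlResult:
    """Mapping-bias regression for one aeQTL: ref-allele fraction ~ genotype.

    ``records`` needs columns ``fraction_ref`` (reference-allele-oriented
    fraction, which a genuine phase effect leaves flat) and ``dosage`` (the
    unphased risk-allele copy count 0/1/2, so the check is invariant to
    parent-label swaps by construction).  A significant slope means the
    apparent aeQTL could be driven by genotype-correlated mapping bias; the
    flag is reported alongside results, never auto-excluded.
    """
    y = records["fraction_ref"].to_numpy(dtype=float)
    x = records["dosage"].to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame({"dosage": x}))
    res = sm.OLS(y, X).fit()
    if res.df_resid <= 0 or res.mse_resid < 1e-24:
        slope, se, t, p = float(res.params["dosage"]), 0.0, 0.0, 1.0
    else:
        slope = float(res.params["dosage"])
        se = float(res.bse["dosage"])
        t = float(res.tvalues["dosage"])
        p = float(res.pvalues["dosage"])
    out = QtlResult(
        pair_id=pair_id, model="bias_check", slope=slope, stderr=se,
        tvalue=t, pvalue=p,
        group_n=tuple(int((x == k).sum()) for k in (0, 1, 2)),
        extras={"flagged": bool(p < 0.05)},
    )
    return out


def add_dosage(records: pd.DataFrame, genotypes: GenotypeTable,
               risk_snp_id: str, risk_allele: str) -> pd.DataFrame:
    """Attach the phase-free risk-allele dosage column used by
    :func:`group_bias_check`."""
    out = records.copy()
    dosage = []
    for s in out["sample"]:
        gt = genotypes.genotype(s, risk_snp_id)
        dosage.append(
            np.nan if gt is None
            else int(gt.allele1 == risk_allele) + int(gt.allele2 == risk_allele))
    out["dosage"] = dosage
    return out


def qq_and_residual_summary(residuals, fitted, groups) -> dict:
    """Regression diagnostics for one fitted aeQTL.

    Returns the theoretical-vs-empirical residual quantile table (QQ data),
    residual spread per genotype group, and the Breusch-Pagan statistic /
    p-value as a numeric heteroscedasticity score.
    """
    resid = np.asarray(residuals, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    g = np.asarray(groups, dtype=int)
    n = resid.size
    std = resid.std(ddof=1) if n > 1 else 0.0
    order = np.sort(resid)
    theo = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"theoretical": theo * (std if std > 0 else 1.0),
                       "empirical": order})
    spread = (
        pd.DataFrame({"group": g, "abs_resid": np.abs(resid), "fitted": fit})
        .groupby("group")
        .agg(n=("abs_resid", "size"), mean_abs_resid=("abs_resid", "mean"),
             mean_fitted=("fitted", "mean"))
    )
    if std > 0 and np.ptp(fit) > 0:
        lm, lm_p, _, _ = het_breuschpagan(resid, sm.add_constant(fit))
        bp_stat, bp_p = float(lm), float(lm_p)
    else:
        bp_stat, bp_p = 0.0, 1.0
    return {"qq": qq, "group_spread": spread,
            "breusch_pagan_stat": bp_stat, "breusch_pagan_pvalue": bp_p}
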