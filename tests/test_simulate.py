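import numpy as np
import pandas as pd
import pytest
import scipy.stats

from aeqtl.io import read_annotation, read_counts, read_covariates, read_phased_vcf
from aeqtl.simulate import (SimConfig, make_toy_fixture, simulate_cohort,
                            simulate_null_batch, write_cohort)


def test_determinism():
    a = simulate_cohort(SimConfig(n_samples=40, n_genes=2, seed=11))
    b = simulate_cohort(SimConfig(n_samples=40, n_genes=2, seed=11))
    c = simulate_cohort(SimConfig(n_samples=40, n_genes=2, seed=12))
    pd.testing.assert_frame_equal(a.counts, b.counts)
    assert (a.genotypes.allele1 == b.genotypes.allele1).all()
    pd.testing.assert_frame_equal(a.expression, b.expression)
    assert not a.counts.equals(c.counts)


def test_config_validation():
    with pytest.raises(ValueError, match="pi"):
        SimConfig(pi=0.0)
    with pytest.raises(ValueError, match="bias_ref"):
        SimConfig(pi=0.6, bias_ref=0.5)
    with pytest.raises(ValueError, match="positive"):
        SimConfig(n_samples=0)
    with pytest.raises(ValueError, match="risk_maf"):
        SimConfig(risk_maf=1.5)


def test_risk_genotypes_in_hwe():
    cfg = SimConfig(n_samples=5000, n_genes=1, risk_maf=0.3, seed=21)
    cohort = simulate_cohort(cfg)
    hap = cohort.truth["genes"][0]["risk_hap"]
    dosage = hap.sum(axis=1)
    obs = np.array([(dosage == k).sum() for k in (0, 1, 2)])
    p, n = 0.3, 5000
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    assert scipy.stats.chi2.sf(chi2, df=2) > 1e-3


def test_group_fraction_means_follow_pi():
    cfg = SimConfig(n_samples=2000, n_genes=1, pi=0.6, depth_mean=100, seed=22)
    cohort = simulate_cohort(cfg)
    g = cohort.truth["genes"][0]
    counts = cohort.counts.set_index(["sample", "snp_id"])
    samples = cohort.genotypes.samples
    fracs = {0: [], 1: [], 2: []}
    for t in g["txsnps"]:
        het = t["het"]
        ref_on_p1 = ~t["alt_on_hap"][:, 0]
        for i in np.flatnonzero(het):
            row = counts.loc[(samples[i], t["txsnp_id"])]
            p1 = row["ref_count"] if ref_on_p1[i] else row["alt_count"]
            fracs[g["group_ref_coded"][i]].append(p1 / (row["ref_count"]
                                                        + row["alt_count"]))
    # ref-coded group 0 has the risk allele on parent 2: share 1 - pi
    assert np.mean(fracs[0]) == pytest.approx(0.4, abs=0.01)
    assert np.mean(fracs[1]) == pytest.approx(0.5, abs=0.01)
    assert np.mean(fracs[2]) == pytest.approx(0.6, abs=0.01)


def test_binomial_read_variance():
    cfg = SimConfig(n_samples=2000, n_genes=1, txsnps_per_gene=1, pi=0.5,
                    depth_mean=100, seed=23)
    cohort = simulate_cohort(cfg)
    t = cohort.truth["genes"][0]["txsnps"][0]
    het = t["het"]
    sub = cohort.counts[np.asarray(het)]
    depth = (sub["ref_count"] + sub["alt_count"]).to_numpy(float)
    frac = sub["ref_count"].to_numpy(float) / depth
    observed = frac.var(ddof=1)
    expected = float(np.mean(0.25 / depth))  # p(1-p)/n at p = 0.5
    assert observed == pytest.approx(expected, rel=0.10)


def test_overdispersion_inflates_variance():
    kw = dict(n_samples=1500, n_genes=1, txsnps_per_gene=1, pi=0.5,
              depth_mean=100, seed=24)
    tight = simulate_cohort(SimConfig(**kw))
    wide = simulate_cohort(SimConfig(rho=0.05, **kw))

    def het_frac_var(cohort):
        t = cohort.truth["genes"][0]["txsnps"][0]
        sub = cohort.counts[np.asarray(t["het"])]
        tot = (sub["ref_count"] + sub["alt_count"]).to_numpy(float)
        return (sub["ref_count"] / tot).var(ddof=1)

    assert het_frac_var(wide) > 2 * het_frac_var(tight)


def test_bias_shifts_ref_fraction():
    kw = dict(n_samples=1000, n_genes=1, pi=0.5, depth_mean=100, seed=25)
    plain = simulate_cohort(SimConfig(**kw))
    biased = simulate_cohort(SimConfig(bias_ref=0.05, **kw))

    def global_ref(cohort):
        from aeqtl.bias import ref_fraction_summary
        return ref_fraction_summary(cohort.counts, cohort.genotypes).global_mean

    assert abs(global_ref(plain) - 0.5) < 0.01
    assert global_ref(biased) == pytest.approx(0.55, abs=0.01)


def test_switch_errors_flip_het_calls():
    kw = dict(n_samples=50, n_genes=1, seed=26)
    clean = simulate_cohort(SimConfig(**kw))
    flipped = simulate_cohort(SimConfig(switch_error_rate=1.0, **kw))
    het = clean.genotypes.allele1 != clean.genotypes.allele2
    assert (flipped.genotypes.allele1[het] == clean.genotypes.allele2[het]).all()
    assert (flipped.genotypes.allele1[~het] == clean.genotypes.allele1[~het]).all()


def test_null_batch_forces_pi_half():
    cohort = simulate_null_batch(SimConfig(pi=0.9, n_samples=10, seed=27), 3)
    assert cohort.truth["config"].pi == 0.5
    assert len(cohort.truth["genes"]) == 3


def test_write_cohort_round_trip(tmp_path):
    cohort = simulate_cohort(SimConfig(n_samples=20, n_genes=2, seed=28))
    paths = write_cohort(cohort, tmp_path)
    geno = read_phased_vcf(paths["vcf"])
    assert geno.samples == cohort.genotypes.samples
    for sid in cohort.genotypes.snps.index:
        jo = cohort.genotypes._snp_idx[sid]
        jb = geno._snp_idx[sid]
        assert (geno.allele1[:, jb] == cohort.genotypes.allele1[:, jo]).all()
    counts = read_counts(paths["counts"])
    pd.testing.assert_frame_equal(counts, cohort.counts)
    ann = read_annotation(paths["annotation"], "gff3")
    pd.testing.assert_frame_equal(ann.genes, cohort.annotation.genes)
    cov = read_covariates(paths["covariates"])
    assert list(cov.index) == cohort.genotypes.samples


def test_toy_fixture_structure(toy, golden):
    assert len(toy.genotypes.samples) == 14
    assert set(toy.annotation.genes.index) == {"geneA", "geneB"}
    assert toy.risk_snps.loc["rs_toy", "risk_allele"] == "G"
    assert set(golden["fractions"]) == {"geneA", "geneB"}
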