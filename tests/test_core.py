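import numpy as np
import pytest

from aeqtl.core import (PhaseError, build_fraction_records, classify_het,
                        filter_txsnp_sample, phase_orient, risk_group,
                        summarize_region)
from aeqtl.core import testable as is_testable
from aeqtl.regions import build_regions
from aeqtl.types import FilterConfig, PhasedGenotype

CFG = FilterConfig()


def test_classify_het():
    assert classify_het(PhasedGenotype("A", "G", True))
    assert classify_het(PhasedGenotype("A", "G", False))
    assert not classify_het(PhasedGenotype("A", "A", True))


@pytest.mark.parametrize("ref,alt,expected", [
    (9, 50, False),    # minor allele below 10 reads
    (15, 200, False),  # minor share 15/215 < 10%
    (20, 30, True),
    (10, 90, True),    # exactly at both thresholds
    (10, 91, False),   # 10/101 just under 10%
    (0, 0, False),
    (0, 100, False),
])
def test_filter_txsnp_sample(ref, alt, expected):
    assert filter_txsnp_sample(ref, alt, CFG) is expected


def test_filter_negative_count_raises():
    with pytest.raises(ValueError):
        filter_txsnp_sample(-1, 10, CFG)


def test_phase_orient():
    het_ra = PhasedGenotype("T", "C", True)   # ref on parent 1
    het_ar = PhasedGenotype("C", "T", True)   # alt on parent 1
    assert phase_orient(30, 10, het_ra, "T", "C") == (30, 10)
    assert phase_orient(30, 10, het_ar, "T", "C") == (10, 30)
    with pytest.raises(PhaseError, match="homozygous"):
        phase_orient(30, 10, PhasedGenotype("T", "T", True), "T", "C")
    with pytest.raises(PhaseError, match="unphased"):
        phase_orient(30, 10, PhasedGenotype("T", "C", False), "T", "C")
    with pytest.raises(ValueError, match="not ref/alt"):
        phase_orient(30, 10, PhasedGenotype("A", "G", True), "T", "C")


def test_risk_group():
    assert risk_group(PhasedGenotype("G", "A", True), "G") == 0
    assert risk_group(PhasedGenotype("A", "A", True), "G") == 1
    assert risk_group(PhasedGenotype("G", "G", True), "G") == 1
    assert risk_group(PhasedGenotype("A", "G", True), "G") == 2
    with pytest.raises(PhaseError):
        risk_group(PhasedGenotype("A", "G", False), "G")
    with pytest.raises(ValueError, match="absent"):
        risk_group(PhasedGenotype("A", "G", True), "T")


def test_summarize_region():
    frac, n, reads = summarize_region([30, 10], [10, 10], "mean")
    assert frac == pytest.approx((0.75 + 0.5) / 2)
    assert (n, reads) == (2, 60)
    frac_p, _, _ = summarize_region([30, 10], [10, 10], "pooled")
    assert frac_p == pytest.approx(40 / 60)
    with pytest.raises(ValueError, match="no usable"):
        summarize_region([], [], "mean")
    with pytest.raises(ValueError, match="unknown summary"):
        summarize_region([1], [1], "median")


@pytest.mark.parametrize("groups,expected", [
    ([0] * 5 + [2] * 5, True),          # 5/0/5: two groups at the minimum
    ([0] * 4 + [1] * 100 + [2] * 4, False),  # only one group reaches 5
    ([0] * 5, False),
    ([], False),
])
def test_testable(groups, expected):
    assert is_testable(groups, CFG) is expected


def test_fraction_records_toy_gene_a(toy, golden):
    regions = {r.region_id: r for r in build_regions(toy.annotation, toy.counts)}
    records, funnel = build_fraction_records(
        toy.counts, toy.genotypes, regions["geneA"], "rs_toy", "A", CFG)
    want = golden["fractions"]["geneA"]
    assert set(records["sample"]) == set(want)
    for _, row in records.iterrows():
        g = want[row["sample"]]
        assert row["fraction_p1"] == pytest.approx(g["fraction_p1"])
        assert row["group"] == g["group"]
        assert row["n_txsnps"] == g["n_txsnps"]
    assert funnel.testable


def test_fraction_records_double_failure_counted_twice(toy):
    # S13 at tx3 has (3, 40): fails both the 10-read and the 10% rules
    regions = {r.region_id: r for r in build_regions(toy.annotation, toy.counts)}
    _, funnel = build_fraction_records(
        toy.counts, toy.genotypes, regions["geneB"], "rs_toy", "A", CFG)
    assert funnel.n_fail_reads == 1
    assert funnel.n_fail_minor == 1
    assert funnel.n_candidates - funnel.n_pass == 1  # one record lost


def test_fraction_records_per_txsnp_mode(toy):
    regions = {r.region_id: r for r in build_regions(toy.annotation, toy.counts)}
    records, _ = build_fraction_records(
        toy.counts, toy.genotypes, regions["geneA"], "rs_toy", "A", CFG,
        per_txsnp=True)
    # S01 is het and passing at both tx1 and tx4
    s01 = records[records["sample"] == "S01"]
    assert sorted(s01["txsnp_id"]) == ["tx1", "tx4"]
    assert (s01["n_txsnps"] == 1).all()
    f = s01.set_index("txsnp_id")["fraction_p1"]
    assert f["tx1"] == pytest.approx(0.75)  # T|C with (30, 10): p1 = ref = 30
    assert f["tx4"] == pytest.approx(0.45)  # T|C with (18, 22)


def test_fraction_records_mean_vs_pooled(toy):
    regions = {r.region_id: r for r in build_regions(toy.annotation, toy.counts)}
    pooled, _ = build_fraction_records(
        toy.counts, toy.genotypes, regions["geneA"], "rs_toy", "A", CFG,
        summary="pooled")
    s01 = pooled.set_index("sample").loc["S01"]
    # tx1 (30, 10) + tx4 (18, 22) pooled: (30 + 18) / 80
    assert s01["fraction_p1"] == pytest.approx(48 / 80)
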