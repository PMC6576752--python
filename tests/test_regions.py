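import pandas as pd
import pytest

from aeqtl.regions import (build_regions, pair_risk_snps, pairs_table,
                           span_distance)
from aeqtl.types import AnnotationSet, COUNT_COLUMNS


def _ann(genes, exons=None):
    df = pd.DataFrame(genes).set_index("gene_id")
    if exons is None:
        exons = {g: [(int(r["start"]), int(r["end"]))] for g, r in df.iterrows()}
    return AnnotationSet(df, exons)


def _counts(rows):
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


EMPTY = _counts([])


def test_transitive_merge():
    # a overlaps b, b overlaps c, a does not overlap c: still one region
    ann = _ann([
        {"gene_id": "a", "chrom": "chr1", "strand": "+", "start": 0, "end": 100},
        {"gene_id": "b", "chrom": "chr1", "strand": "+", "start": 50, "end": 200},
        {"gene_id": "c", "chrom": "chr1", "strand": "+", "start": 150, "end": 300},
        {"gene_id": "d", "chrom": "chr1", "strand": "+", "start": 300, "end": 400},
    ])
    regions = {r.region_id: r for r in build_regions(ann, EMPTY)}
    assert set(regions) == {"a+b+c", "d"}
    assert regions["a+b+c"].span == (0, 300)


def test_abutting_spans_not_merged():
    ann = _ann([
        {"gene_id": "a", "chrom": "chr1", "strand": "+", "start": 0, "end": 100},
        {"gene_id": "b", "chrom": "chr1", "strand": "+", "start": 100, "end": 200},
    ])
    assert sorted(r.region_id for r in build_regions(ann, EMPTY)) == ["a", "b"]


def test_intronic_txsnp_joins_no_region(toy):
    regions = {r.region_id: r for r in build_regions(toy.annotation, toy.counts)}
    assert regions["geneA"].txsnp_ids == ["tx1", "tx4"]
    assert regions["geneB"].txsnp_ids == ["tx3"]
    assert not any("tx2" in r.txsnp_ids for r in regions.values())


def test_chromosome_mismatch_fatal(toy):
    bad = toy.counts.copy()
    bad.loc[0, "chrom"] = "1"  # naming scheme mismatch
    with pytest.raises(ValueError, match="absent from annotation"):
        build_regions(toy.annotation, bad)


def test_span_distance_signs():
    span = (1000, 2000)  # half-open
    assert span_distance(1000, span) == 0
    assert span_distance(1999, span) == 0
    assert span_distance(2000, span) == -1   # gene toward lower coordinates
    assert span_distance(2500, span) == -501
    assert span_distance(999, span) == 1     # gene toward higher coordinates
    assert span_distance(500, span) == 500


def _one_gene_regions(start, end):
    ann = _ann([{"gene_id": "g", "chrom": "chr1", "strand": "+",
                 "start": start, "end": end}])
    return build_regions(ann, EMPTY)


def test_window_boundary_inclusive():
    regions = _one_gene_regions(1_000_000, 1_010_000)
    snp_at = lambda pos0: pd.DataFrame(
        [{"snp_id": "rs", "chrom": "chr1", "pos": pos0 + 1,
          "risk_allele": "G"}]).set_index("snp_id")
    exactly = pair_risk_snps(regions, snp_at(800_000))   # |d| = 200,000
    beyond = pair_risk_snps(regions, snp_at(799_999))    # |d| = 200,001
    assert len(exactly) == 1 and exactly[0].distance == 200_000
    assert beyond == []


def test_pair_ranking_and_table():
    ann = _ann([
        {"gene_id": "near", "chrom": "chr1", "strand": "+",
         "start": 10_000, "end": 20_000},
        {"gene_id": "far", "chrom": "chr1", "strand": "+",
         "start": 100_000, "end": 110_000},
        {"gene_id": "other", "chrom": "chr2", "strand": "+",
         "start": 10_000, "end": 20_000},
    ])
    regions = build_regions(ann, EMPTY)
    risk = pd.DataFrame([{"snp_id": "rs", "chrom": "chr1", "pos": 5_001,
                          "risk_allele": "G"}]).set_index("snp_id")
    tbl = pairs_table(pair_risk_snps(regions, risk))
    assert list(tbl["region_id"]) == ["near", "far"]
    assert list(tbl["distance_rank"]) == [1, 2]
    assert list(tbl["distance"]) == [5_000, 95_000]  # both genes 3' of the SNP


def test_intragenic_snp_distance_zero():
    regions = _one_gene_regions(1_000, 2_000)
    risk = pd.DataFrame([{"snp_id": "rs", "chrom": "chr1", "pos": 1_500,
                          "risk_allele": "G"}]).set_index("snp_id")
    pairs = pair_risk_snps(regions, risk)
    assert pairs[0].distance == 0 and pairs[0].distance_rank == 1


def test_window_must_be_positive():
    with pytest.raises(ValueError):
        pair_risk_snps([], pd.DataFrame(), window=0)
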