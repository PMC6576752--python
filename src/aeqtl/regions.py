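"""txSNP-region construction and risk-SNP <-> gene pairing.

Each txSNP-region corresponds to one gene; genes whose transcription spans
overlap (transitively) are merged into a single region.  txSNPs are region
members only when they fall inside an exon/UTR interval.  Risk SNPs pair
with every region whose nearest gene-span boundary lies within the distance
window (default 200 kb); an intragenic SNP has distance 0.
"""
from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .types import AnnotationSet, RiskGenePair, TxSnpRegion


def build_regions(annotation: AnnotationSet, counts: pd.DataFrame) -> list[TxSnpRegion]:
    """Partition genes into txSNP-regions and attach exonic txSNPs.

    Chromosome names must agree between annotation and counts; a txSNP
    chromosome absent from the annotation is fatal.
    """
    ann_chroms = set(annotation.genes["chrom"])
    count_chroms = set(counts["chrom"].unique())
    stray = count_chroms - ann_chroms
    if stray:
        raise ValueError(
            f"count-table chromosome {sorted(stray)[0]!r} absent from annotation "
            "(naming scheme mismatch?)"
        )

    regions: list[TxSnpRegion] = []
    for chrom, genes in annotation.genes.groupby("chrom", sort=True):
        # transitively merge overlapping transcription spans
        ordered = genes.sort_values(["start", "end"])
        clusters: list[list[str]] = []
        cluster_end = None
        for gid, g in ordered.iterrows():
            if cluster_end is None or g["start"] >= cluster_end:
                clusters.append([gid])
                cluster_end = g["end"]
            else:
                clusters[-1].append(gid)
                cluster_end = max(cluster_end, g["end"])
        for members in clusters:
            members = sorted(members)
            span = (
                int(genes.loc[members, "start"].min()),
                int(genes.loc[members, "end"].max()),
            )
            exons = _merge_intervals(
                [iv for gid in members for iv in annotation.exons[gid]]
            )
            regions.append(
                TxSnpRegion(
                    region_id="+".join(members),
                    gene_ids=members,
                    chrom=chrom,
                    span=span,
                    exon_intervals=exons,
                    txsnp_ids=[],
                )
            )

    # assign txSNPs falling in exon/UTR intervals (positions are 1-based in
    # the count table; internal intervals are 0-based half-open)
    trees: dict[str, IntervalTree] = {}
    by_region = {r.region_id: r for r in regions}
    for r in regions:
        tree = trees.setdefault(r.chrom, IntervalTree())
        for s, e in r.exon_intervals:
            tree.addi(s, e, r.region_id)
    snps = counts[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
    for _, row in snps.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for hit in tree[row["pos"] - 1]:
            by_region[hit.data].txsnp_ids.append(row["snp_id"])
    for r in regions:
        r.txsnp_ids = sorted(set(r.txsnp_ids))
    return regions


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def span_distance(pos0: int, span: tuple[int, int]) -> int:
    """Signed bp distance from a 0-based position to a half-open span.

    0 inside the span; negative when the span lies toward lower coordinates
    (gene entirely 5' of the SNP on the genome axis), positive toward higher.
    """
    s, e = span
    if s <= pos0 < e:
        return 0
    if pos0 >= e:
        return -(pos0 - (e - 1))
    return s - pos0


def pair_risk_snps(
    regions: list[TxSnpRegion],
    risk_snps: pd.DataFrame,
    window: int = 200_000,
) -> list[RiskGenePair]:
    """Pair each risk SNP with every region within ``window`` bp.

    Distance is measured from the SNP position to the nearest boundary of
    the nearest member gene span (not the TSS).  Ranks are assigned per risk
    SNP by |distance|, ties broken by region id.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pairs: list[RiskGenePair] = []
    for snp_id, rec in risk_snps.iterrows():
        pos0 = int(rec["pos"]) - 1
        cands = []
        for r in regions:
            if r.chrom != rec["chrom"]:
                continue
            d = span_distance(pos0, r.span)
            if abs(d) <= window:
                cands.append((abs(d), r.region_id, d))
        cands.sort()
        for rank, (_, rid, d) in enumerate(cands, start=1):
            pairs.append(RiskGenePair(snp_id, rid, d, rank))
    return pairs


def pairs_table(pairs: list[RiskGenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"risk_snp_id": p.risk_snp_id, "region_id": p.region_id,
          "distance": p.distance, "distance_rank": p.distance_rank}
         for p in pairs],
        columns=["risk_snp_id", "region_id", "distance", "distance_rank"],
    )
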