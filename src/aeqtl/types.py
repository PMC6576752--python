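"""In-memory containers shared by every pipeline stage.

All genomic intervals are stored 0-based half-open; VCF and GFF3 positions
are converted on read and back on write.  Alleles are opaque strings so that
indel codes ("D"/"I") and multi-base alleles are representable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd


class PhasedGenotype(NamedTuple):
    """An ordered allele pair for one sample at one SNP.

    ``allele1`` is the allele on the parent-1 haplotype when ``phased`` is
    True; for unphased genotypes the order is arbitrary and phase-dependent
    operations must refuse the record.
    """

    allele1: str
    allele2: str
    phased: bool

    @property
    def heterozygous(self) -> bool:
        return self.allele1 != self.allele2


#: Count-table column order used by readers, writers and the simulator.
COUNT_COLUMNS = ["sample", "snp_id", "chrom", "pos", "ref_count", "alt_count"]


@dataclass
class GenotypeTable:
    """Phased genotypes for a cohort: samples x SNPs.

    ``allele1``/``allele2`` are object arrays of allele strings (``None`` for
    missing); ``phased`` is boolean.  Column order follows ``snps.index``.
    """

    samples: list[str]
    snps: pd.DataFrame  # index: snp_id; columns: chrom, pos (1-based), ref, alt
    allele1: np.ndarray
    allele2: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.snps)
        for arr in (self.allele1, self.allele2, self.phased):
            if arr.shape != (n, m):
                raise ValueError(
                    f"genotype array shape {arr.shape} != (samples, snps) = {(n, m)}"
                )
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._snp_idx = {s: j for j, s in enumerate(self.snps.index)}

    def genotype(self, sample: str, snp_id: str) -> Optional[PhasedGenotype]:
        """Genotype of ``sample`` at ``snp_id``; None when missing."""
        i, j = self._sample_idx[sample], self._snp_idx[snp_id]
        a1 = self.allele1[i, j]
        if a1 is None:
            return None
        return PhasedGenotype(a1, self.allele2[i, j], bool(self.phased[i, j]))

    def validate_alleles(self) -> None:
        """Check every non-missing call is drawn from its SNP's ref/alt."""
        for j, (snp_id, rec) in enumerate(self.snps.iterrows()):
            valid = {rec["ref"], rec["alt"]}
            for arr in (self.allele1, self.allele2):
                col = arr[:, j]
                bad = [a for a in col if a is not None and a not in valid]
                if bad:
                    raise ValueError(
                        f"SNP {snp_id}: allele {bad[0]!r} not in ref/alt {valid}"
                    )

    def flipped(self, snps: Optional[list[str]] = None) -> "GenotypeTable":
        """Return a copy with parent-1/parent-2 labels swapped at ``snps``
        (all SNPs when None), for every sample.

        Used by the flip-symmetry diagnostic: relabeling the haplotype at
        every SNP maps downstream parent-1 fractions f -> 1-f and risk
        groups g -> 2-g jointly (the fit is invariant); relabeling only the
        risk SNP maps g -> 2-g with fractions untouched, which negates the
        aeQTL slope and leaves the p-value identical.
        """
        a1, a2 = self.allele1.copy(), self.allele2.copy()
        cols = (
            slice(None)
            if snps is None
            else [self._snp_idx[s] for s in snps]
        )
        a1[:, cols], a2[:, cols] = (
            self.allele2[:, cols].copy(),
            self.allele1[:, cols].copy(),
        )
        return GenotypeTable(
            list(self.samples), self.snps.copy(), a1, a2, self.phased.copy()
        )


@dataclass
class AnnotationSet:
    """Gene models: transcription spans plus exon (incl. UTR) intervals.

    ``genes``: index gene_id; columns chrom, strand, start, end (0-based
    half-open span).  ``exons``: gene_id -> list of (start, end) half-open
    intervals, each contained in the gene span.
    """

    genes: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        for gid, ivs in self.exons.items():
            span = self.genes.loc[gid]
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"gene {gid}: empty exon interval [{s},{e})")
                if s < span["start"] or e > span["end"]:
                    raise ValueError(
                        f"gene {gid}: exon [{s},{e}) outside span "
                        f"[{span['start']},{span['end']})"
                    )


@dataclass
class TxSnpRegion:
    """The txSNPs belonging to one gene (or merged overlapping genes)."""

    region_id: str
    gene_ids: list[str]
    chrom: str
    span: tuple[int, int]  # union of member gene spans, half-open
    exon_intervals: list[tuple[int, int]]  # merged, sorted, half-open
    txsnp_ids: list[str]


@dataclass
class RiskGenePair:
    """A risk-SNP paired with a txSNP-region inside the distance window."""

    risk_snp_id: str
    region_id: str
    distance: int  # signed bp to nearest gene-span boundary; 0 inside span
    distance_rank: int  # 1 = nearest region for this risk-SNP


@dataclass
class FilterConfig:
    """QC thresholds applied per sample x txSNP and per pair.

    Defaults: >=10 reads from each allele, >=10% of expression from the less
    expressed allele, and >=5 usable individuals in >=2 genotype groups.
    """

    min_reads_per_allele: int = 10
    min_minor_fraction: float = 0.10
    min_group_n: int = 5
    min_groups: int = 2

    def __post_init__(self) -> None:
        if self.min_reads_per_allele < 0 or not 0 <= self.min_minor_fraction <= 0.5:
            raise ValueError("invalid read/minor-fraction thresholds")
        if self.min_group_n < 0 or not 1 <= self.min_groups <= 3:
            raise ValueError("invalid group-count thresholds")


@dataclass
class QtlResult:
    """One fitted association test."""

    pair_id: str
    model: str  # aeqtl_gene | aeqtl_txsnp | eqtl | interaction | variance_test | bias_check
    slope: float
    stderr: float
    tvalue: float
    pvalue: float
    qvalue: Optional[float] = None
    group_n: tuple[int, int, int] = (0, 0, 0)
    direction: Optional[str] = None  # "up"/"down" w.r.t. designated risk allele
    covariates: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(sum(self.group_n))
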