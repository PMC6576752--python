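"""Readers and writers for the external formats and the run configuration.

Formats: phased VCF (genotypes), TSV allele-count tables, BED12/GFF3 gene
annotation, TSV risk-SNP lists and covariates, TSV results, and a plain
``key = value`` run-config file.  Everything downstream works on the
validated containers in :mod:`aeqtl.types`.
"""
from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import COUNT_COLUMNS, AnnotationSet, GenotypeTable, QtlResult


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def read_phased_vcf(
    path: str | Path,
    region: Optional[str] = None,
    split_multiallelic: bool = False,
) -> GenotypeTable:
    """Read phased genotypes from a VCF into a :class:`GenotypeTable`.

    ``|``-separated GT fields are parsed as (parent-1, parent-2) allele
    pairs; ``/``-separated ones are kept but flagged unphased so that
    phase-dependent operations reject them.  Multiallelic records are
    excluded by default (``split_multiallelic=True`` emits one biallelic
    record per ALT allele, with calls carrying other ALTs set missing).

    ``region`` is ``"chrom"`` or ``"chrom:start-end"`` (1-based inclusive).
    """
    chrom_filt = start_filt = end_filt = None
    if region is not None:
        m = _REGION_RE.match(region)
        if m is None:
            raise ValueError(f"bad region string: {region!r}")
        chrom_filt = m.group(1)
        if m.group(2):
            start_filt, end_filt = int(m.group(2)), int(m.group(3))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns / GT field")

    snp_rows: list[dict] = []
    a1_cols: list[np.ndarray] = []
    a2_cols: list[np.ndarray] = []
    ph_cols: list[np.ndarray] = []

    for var in vcf:
        if chrom_filt is not None:
            if var.CHROM != chrom_filt:
                continue
            if start_filt is not None and not (start_filt <= var.POS <= end_filt):
                continue
        alts = list(var.ALT)
        if len(alts) != 1:
            if not split_multiallelic:
                continue
        else:
            alts = [alts[0]]
        genos = var.genotypes  # list of [a1_idx, a2_idx, phased]
        for alt_i, alt in enumerate(alts, start=1):
            alleles = {0: var.REF, alt_i: alt}
            a1 = np.empty(len(samples), dtype=object)
            a2 = np.empty(len(samples), dtype=object)
            ph = np.zeros(len(samples), dtype=bool)
            for i, g in enumerate(genos):
                if len(g) < 3:
                    raise FormatError(
                        f"{path}: malformed GT for sample {samples[i]} at "
                        f"{var.CHROM}:{var.POS}"
                    )
                i1, i2, phased = g[0], g[1], bool(g[-1])
                if i1 < 0 or i2 < 0:
                    continue  # missing genotype propagates as missing
                if i1 not in alleles or i2 not in alleles:
                    # carries an ALT other than the one being emitted
                    continue
                a1[i], a2[i], ph[i] = alleles[i1], alleles[i2], phased
            sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
            if len(alts) > 1:
                sid = f"{sid}_{alt}"
            snp_rows.append(
                {"snp_id": sid, "chrom": var.CHROM, "pos": var.POS,
                 "ref": var.REF, "alt": alt}
            )
            a1_cols.append(a1)
            a2_cols.append(a2)
            ph_cols.append(ph)

    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    snps = snps.set_index("snp_id")
    if snps.index.has_duplicates:
        dup = snps.index[snps.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate SNP id {dup}")
    stack = lambda cols: (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=object)
    )
    table = GenotypeTable(
        samples,
        snps,
        stack(a1_cols),
        stack(a2_cols),
        np.stack(ph_cols, axis=1).astype(bool) if ph_cols
        else np.empty((len(samples), 0), dtype=bool),
    )
    table.validate_alleles()
    return table


# ---------------------------------------------------------------------------
# Allele count tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-sample allele-count table (TSV).

    Columns: sample, snp_id, chrom, pos (1-based), ref_count, alt_count.
    Duplicate (sample, snp_id) rows, negative or non-integer counts, and
    unknown columns are fatal, reported with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "snp_id": str, "chrom": str})
    unknown = [c for c in df.columns if c not in COUNT_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unknown columns {unknown}")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("ref_count", "alt_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is row 1
            raise FormatError(f"{path}: invalid {col} at line {row}")
        df[col] = vals.astype(int)
    dup = df.duplicated(subset=["sample", "snp_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise FormatError(f"{path}: duplicate (sample, snp_id) at line {row}")
    df["pos"] = df["pos"].astype(int)
    return df[COUNT_COLUMNS]


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation (BED12 / GFF3)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, dialect: str) -> AnnotationSet:
    """Read gene models from BED12 (0-based half-open) or GFF3 (1-based
    closed), unifying to the internal half-open 0-based convention."""
    if dialect == "bed":
        return _read_bed12(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_bed12(path: str | Path) -> AnnotationSet:
    rows, exons = [], {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 requires 12 columns")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            if end <= start:
                raise FormatError(f"{path}:{ln}: interval end <= start")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{ln}: block count mismatch")
            rows.append({"gene_id": name, "chrom": chrom, "strand": strand,
                         "start": start, "end": end})
            exons[name] = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
    return _finish_annotation(rows, exons)


def _read_gff3(path: str | Path) -> AnnotationSet:
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 requires 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = f
            start, end = int(start), int(end)
            if end < start:
                raise FormatError(f"{path}:{ln}: interval end < start")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            # 1-based closed -> 0-based half-open
            s0, e0 = start - 1, end
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{ln}: gene without ID attribute")
                genes[gid] = {"gene_id": gid, "chrom": chrom, "strand": strand,
                              "start": s0, "end": e0}
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent") or attr.get("gene_id")
                if parent is None:
                    raise FormatError(f"{path}:{ln}: {ftype} without Parent")
                exons.setdefault(parent, []).append((s0, e0))
    for gid in genes:
        exons.setdefault(gid, [(genes[gid]["start"], genes[gid]["end"])])
    return _finish_annotation(list(genes.values()), exons)


def _finish_annotation(rows: list[dict], exons: dict) -> AnnotationSet:
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    genes = genes.set_index("gene_id")
    if genes.index.has_duplicates:
        dup = genes.index[genes.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup}")
    return AnnotationSet(genes, {g: sorted(iv) for g, iv in exons.items()})


def write_gff3(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet back to GFF3 (exact inverse of _read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, g in ann.genes.iterrows():
            fh.write(
                f"{g['chrom']}\taeqtl\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={gid}\n"
            )
            for s, e in ann.exons[gid]:
                fh.write(
                    f"{g['chrom']}\taeqtl\texon\t{s + 1}\t{e}\t.\t"
                    f"{g['strand']}\t.\tParent={gid}\n"
                )


# ---------------------------------------------------------------------------
# Risk SNPs, covariates, results
# ---------------------------------------------------------------------------

def read_risk_snps(path: str | Path) -> pd.DataFrame:
    """TSV with columns snp_id, chrom, pos (1-based), risk_allele."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str,
                                            "risk_allele": str})
    need = ["snp_id", "chrom", "pos", "risk_allele"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["pos"] = df["pos"].astype(int)
    return df[need].set_index("snp_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Per-sample covariate TSV; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise FormatError(f"{path}: covariate table needs a 'sample' column")
    return df.set_index("sample")


RESULT_COLUMNS = [
    "pair_id", "model", "snp_id", "region_id", "distance", "distance_rank",
    "ref", "alt", "direction", "slope", "stderr", "tvalue", "pvalue", "qvalue",
    "n_txsnps", "max_reads", "n_group0", "n_group1", "n_group2",
]


def write_results(results: list[QtlResult], path: str | Path) -> None:
    """Write fitted QTL results as a TSV with a stable column order."""
    rows = []
    for r in results:
        ex = r.extras
        rows.append({
            "pair_id": r.pair_id, "model": r.model,
            "snp_id": ex.get("snp_id", ""), "region_id": ex.get("region_id", ""),
            "distance": ex.get("distance", ""),
            "distance_rank": ex.get("distance_rank", ""),
            "ref": ex.get("ref", ""), "alt": ex.get("alt", ""),
            "direction": r.direction if r.direction is not None else "",
            "slope": r.slope, "stderr": r.stderr, "tvalue": r.tvalue,
            "pvalue": r.pvalue,
            "qvalue": r.qvalue if r.qvalue is not None else "",
            "n_txsnps": ex.get("n_txsnps", ""), "max_reads": ex.get("max_reads", ""),
            "n_group0": r.group_n[0], "n_group1": r.group_n[1],
            "n_group2": r.group_n[2],
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline thresholds, with the study defaults.

    window: risk-SNP-to-gene pairing window in bp.
    alpha: FDR level; gene-level and txSNP-level families corrected separately.
    k_geno_pcs / k_expr_pcs: genotype and expression principal components
    entering every model alongside age and sex.
    """

    window: int = 200_000
    alpha: float = 0.05
    k_geno_pcs: int = 3
    k_expr_pcs: int = 10
    min_reads_per_allele: int = 10
    min_minor_fraction: float = 0.10
    min_group_n: int = 5
    min_groups: int = 2
    group_coding: str = "numeric"  # numeric | categorical
    region_summary: str = "mean"  # mean | pooled
    eqtl_transform: str = "log2"  # log2 | none
    split_multiallelic: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain ``key = value`` config file (# comments allowed)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{ln}: expected 'key = value'")
                key, val = (x.strip() for x in line.split("=", 1))
                if key not in fields:
                    raise FormatError(f"{path}:{ln}: unknown config key {key!r}")
                typ = fields[key].type
                if typ in ("int", int):
                    kwargs[key] = int(val)
                elif typ in ("float", float):
                    kwargs[key] = float(val)
                elif typ in ("bool", bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    def filter_config(self):
        from .types import FilterConfig

        return FilterConfig(
            min_reads_per_allele=self.min_reads_per_allele,
            min_minor_fraction=self.min_minor_fraction,
            min_group_n=self.min_group_n,
            min_groups=self.min_groups,
        )
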