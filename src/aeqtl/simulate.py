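"""Synthetic-cohort generator with the statistical structure the aeQTL
model assumes.

Per sample, two haplotypes are drawn under Hardy-Weinberg equilibrium at a
risk SNP and at each gene's transcribed SNPs.  Allelic read counts at a
heterozygous txSNP follow a (beta-)binomial whose parent-1 success
probability is the risk-haplotype expression share pi when the risk allele
sits on parent 1, 1 - pi when it sits on parent 2, and 0.5 when the risk
SNP is homozygous — exactly the three fraction levels the phase-coded
regression tests.  An optional additive reference-mapping bias b shifts the
probability of the allele that maps to the reference base, reproducing the
global ref-fraction inflation that motivates N-masked alignment.  Total
expression is multiplicative in risk-allele dosage, age, sex and log-normal
noise.  Every latent quantity is kept in a truth record.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import AnnotationSet, COUNT_COLUMNS, GenotypeTable

_GENE_SPACING = 1_000_000
_GENE_LENGTH = 10_000
_RISK_OFFSET = 50_000  # risk SNP this many bp 5' of each gene span


@dataclass
class SimConfig:
    """Generator settings.

    pi is the risk-haplotype expression share (0.5 = null); rho the
    beta-binomial intra-site correlation (0 = binomial reads); bias_ref the
    additive reference-allele mapping bias; coupling the probability that a
    txSNP's alt allele rides the risk haplotype (LD between txSNP and risk
    SNP; 0 = independent).  Depth is Poisson at ``depth_mean`` unless
    ``depth_dispersion`` > 0, which switches to negative binomial with that
    Fano overdispersion.  The defaults are a 300-sample cohort at 50x
    allelic depth, a common-variant risk SNP (MAF 0.5) and a clearly
    non-null share pi = 0.6.
    """

    n_samples: int = 300
    n_genes: int = 1
    txsnps_per_gene: int = 3
    risk_maf: float = 0.5
    txsnp_maf: float = 0.3
    coupling: float = 0.0
    pi: float = 0.6
    depth_mean: float = 50.0
    depth_dispersion: float = 0.0
    rho: float = 0.0
    bias_ref: float = 0.0
    bias_genotype_coeff: float = 0.0
    switch_error_rate: float = 0.0
    baseline_expr: float = 100.0
    dosage_effect_expr: float = 0.2
    age_effect_expr: float = 0.002
    sex_effect_expr: float = 0.1
    expr_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise ValueError("pi must lie in (0, 1)")
        for name in ("risk_maf", "txsnp_maf", "coupling", "rho",
                     "switch_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        hi = max(self.pi, 1 - self.pi, 0.5)
        if not 0 <= hi + self.bias_ref < 1 or min(self.pi, 1 - self.pi) + self.bias_ref <= 0:
            raise ValueError("bias_ref pushes an allele probability outside (0, 1)")
        if self.n_samples < 1 or self.n_genes < 1 or self.txsnps_per_gene < 1:
            raise ValueError("sizes must be positive")


@dataclass
class SimulatedCohort:
    """Everything one simulated study produces, plus the latent truth."""

    genotypes: GenotypeTable
    counts: pd.DataFrame
    annotation: AnnotationSet
    risk_snps: pd.DataFrame
    expression: pd.DataFrame  # samples x genes
    covariates: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _draw_counts(rng: np.random.Generator, depth: np.ndarray, p: np.ndarray,
                 rho: float) -> np.ndarray:
    """Successes out of ``depth`` with probability ``p``; beta-binomial when
    rho > 0 (rho is the intra-site correlation)."""
    if rho <= 0:
        return rng.binomial(depth, p)
    conc = (1 - rho) / rho
    a = np.maximum(p * conc, 1e-9)
    b = np.maximum((1 - p) * conc, 1e-9)
    return rng.binomial(depth, rng.beta(a, b))


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate one phased, counted, covariate-laden cohort.

    The same seed yields byte-identical tables."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]

    # covariates
    age = rng.uniform(18, 90, n).round(1)
    sex = rng.integers(0, 2, n)
    rin = np.clip(rng.normal(8.1, 0.9, n), 4.0, 10.0).round(2)
    diagnosis = rng.integers(0, 2, n)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "rin": rin, "diagnosis": diagnosis},
        index=pd.Index(samples, name="sample"),
    )

    snp_rows: list[dict] = []
    gene_rows: list[dict] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    risk_rows: list[dict] = []
    a1_cols: list[np.ndarray] = []
    a2_cols: list[np.ndarray] = []
    count_frames: list[pd.DataFrame] = []
    expr = np.zeros((n, cfg.n_genes))
    truth_genes: list[dict] = []

    chrom = "chr1"
    for g in range(cfg.n_genes):
        gene_id = f"gene{g + 1:04d}"
        gstart = _GENE_SPACING * (g + 1)
        gend = gstart + _GENE_LENGTH
        gene_rows.append({"gene_id": gene_id, "chrom": chrom, "strand": "+",
                          "start": gstart, "end": gend})
        exon1 = (gstart, gstart + _GENE_LENGTH // 2)
        exon2 = (gstart + _GENE_LENGTH // 2 + 1_000, gend)
        exons[gene_id] = [exon1, exon2]

        # risk SNP haplotypes under HWE; allele "G" is the risk/alt allele
        risk_id = f"rs_g{g + 1}"
        risk_pos = gstart - _RISK_OFFSET + 1  # 1-based
        risk_hap = rng.random((n, 2)) < cfg.risk_maf  # True = risk allele
        risk_a1 = np.where(risk_hap[:, 0], "G", "A").astype(object)
        risk_a2 = np.where(risk_hap[:, 1], "G", "A").astype(object)
        snp_rows.append({"snp_id": risk_id, "chrom": chrom, "pos": risk_pos,
                         "ref": "A", "alt": "G"})
        risk_rows.append({"snp_id": risk_id, "chrom": chrom, "pos": risk_pos,
                          "risk_allele": "G"})
        a1_cols.append(risk_a1)
        a2_cols.append(risk_a2)

        # parent-1 read probability per sample from the phased risk genotype
        het = risk_hap[:, 0] != risk_hap[:, 1]
        p1_prob = np.full(n, 0.5)
        p1_prob[het & risk_hap[:, 0]] = cfg.pi
        p1_prob[het & risk_hap[:, 1]] = 1 - cfg.pi

        tx_truth = []
        for t in range(cfg.txsnps_per_gene):
            tx_id = f"tx_g{g + 1}_{t + 1}"
            tx_pos = gstart + 100 * (t + 1) + 1  # inside exon1, 1-based
            # txSNP haplotypes: with prob `coupling` the alt allele rides the
            # risk haplotype, otherwise an independent HWE draw
            coupled = rng.random((n, 2)) < cfg.coupling
            indep = rng.random((n, 2)) < cfg.txsnp_maf
            tx_alt = np.where(coupled, risk_hap, indep)  # True = alt allele
            tx_a1 = np.where(tx_alt[:, 0], "C", "T").astype(object)
            tx_a2 = np.where(tx_alt[:, 1], "C", "T").astype(object)
            snp_rows.append({"snp_id": tx_id, "chrom": chrom, "pos": tx_pos,
                             "ref": "T", "alt": "C"})
            a1_cols.append(tx_a1)
            a2_cols.append(tx_a2)

            if cfg.depth_dispersion > 0:
                r_nb = cfg.depth_mean / cfg.depth_dispersion
                depth = rng.negative_binomial(
                    r_nb, r_nb / (r_nb + cfg.depth_mean), n)
            else:
                depth = rng.poisson(cfg.depth_mean, n)
            depth = np.maximum(depth, 1)

            tx_het = tx_alt[:, 0] != tx_alt[:, 1]
            # probability that a read carries the REF base: parent-1 share if
            # ref sits on parent 1, else the complement; hom sites emit only
            # their allele; the mapping bias then inflates the ref side.
            ref_on_p1 = ~tx_alt[:, 0]
            p_ref = np.where(ref_on_p1, p1_prob, 1 - p1_prob)
            # mapping bias: a global ref shift, plus an optional adversarial
            # component coupled to the risk-allele dosage (for testing the
            # genotype-group bias diagnostic)
            shift = cfg.bias_ref + cfg.bias_genotype_coeff * (
                risk_hap.sum(axis=1) - 1)
            p_ref = np.clip(p_ref + shift, 1e-12, 1 - 1e-12)
            ref_count = np.where(
                tx_het,
                _draw_counts(rng, depth, p_ref, cfg.rho),
                # homozygous sites emit only their own allele
                np.where(tx_alt[:, 0], 0, depth),
            )
            alt_count = depth - ref_count
            count_frames.append(pd.DataFrame({
                "sample": samples, "snp_id": tx_id, "chrom": chrom,
                "pos": tx_pos, "ref_count": ref_count.astype(int),
                "alt_count": alt_count.astype(int),
            }))
            tx_truth.append({"txsnp_id": tx_id, "alt_on_hap": tx_alt,
                             "het": tx_het, "depth": depth})

        # total expression: multiplicative dosage, covariate and noise terms
        dosage = risk_hap.sum(axis=1)
        mu = (cfg.baseline_expr
              * (1 + cfg.dosage_effect_expr * dosage)
              * np.exp(cfg.age_effect_expr * (age - age.mean()))
              * np.exp(cfg.sex_effect_expr * sex))
        expr[:, g] = mu * rng.lognormal(0.0, cfg.expr_noise_sd, n)

        group = np.full(n, 1)
        group[het & ~risk_hap[:, 0]] = 0  # designated (ref "A") on parent 1
        group[het & risk_hap[:, 0]] = 2
        truth_genes.append({
            "gene_id": gene_id, "risk_snp_id": risk_id, "pi": cfg.pi,
            "risk_hap": risk_hap, "group_ref_coded": group,
            "p1_prob": p1_prob, "dosage": dosage, "txsnps": tx_truth,
        })

    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    a1 = np.stack(a1_cols, axis=1)
    a2 = np.stack(a2_cols, axis=1)
    phased = np.ones(a1.shape, dtype=bool)
    if cfg.switch_error_rate > 0:
        het_mask = a1 != a2
        flips = (rng.random(a1.shape) < cfg.switch_error_rate) & het_mask
        a1f = np.where(flips, a2, a1)
        a2f = np.where(flips, a1, a2)
        a1, a2 = a1f.astype(object), a2f.astype(object)

    genotypes = GenotypeTable(samples, snps, a1, a2, phased)
    counts = pd.concat(count_frames, ignore_index=True)[COUNT_COLUMNS]
    annotation = AnnotationSet(
        pd.DataFrame(gene_rows).set_index("gene_id"), exons)
    risk_snps = pd.DataFrame(risk_rows).set_index("snp_id")
    expression = pd.DataFrame(
        expr, index=pd.Index(samples, name="sample"),
        columns=[g["gene_id"] for g in truth_genes])
    return SimulatedCohort(
        genotypes, counts, annotation, risk_snps, expression, covariates,
        truth={"config": cfg, "genes": truth_genes},
    )


def simulate_null_batch(cfg: SimConfig, n_genes: int) -> SimulatedCohort:
    """A batch of independent genes with no cis effect (pi forced to 0.5),
    for FDR-control and p-uniformity checks."""
    return simulate_cohort(replace(cfg, pi=0.5, n_genes=n_genes))


# ---------------------------------------------------------------------------
# File emission (the same formats io reads back)
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeTable, path: str | Path) -> None:
    """Write the genotype table as an uncompressed phased VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        order = genotypes.snps.assign(_j=range(len(genotypes.snps)))
        order = order.sort_values(["chrom", "pos"])
        for snp_id, rec in order.iterrows():
            j = int(rec["_j"])
            cells = []
            for i in range(len(genotypes.samples)):
                a1 = genotypes.allele1[i, j]
                if a1 is None:
                    cells.append("./.")
                    continue
                a2 = genotypes.allele2[i, j]
                idx = {rec["ref"]: "0", rec["alt"]: "1"}
                sep = "|" if genotypes.phased[i, j] else "/"
                cells.append(f"{idx[a1]}{sep}{idx[a2]}")
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{snp_id}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the formats the readers consume."""
    from .io import write_counts, write_gff3

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.gff3",
        "risk_snps": out / "risk_snps.tsv",
        "expression": out / "expression.tsv",
        "covariates": out / "covariates.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    write_counts(cohort.counts, paths["counts"])
    write_gff3(cohort.annotation, paths["annotation"])
    cohort.risk_snps.reset_index().to_csv(paths["risk_snps"], sep="\t", index=False)
    cohort.expression.reset_index().to_csv(paths["expression"], sep="\t", index=False)
    cohort.covariates.reset_index().to_csv(paths["covariates"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Hand-checkable toy fixture
# ---------------------------------------------------------------------------

def make_toy_fixture() -> SimulatedCohort:
    """A tiny deterministic dataset exercising every filter branch.

    14 samples, one risk SNP (chr1:1000, ref A / alt G, risk allele G), two
    genes.  geneA (span 5,000-15,000) carries exonic txSNPs tx1 and tx4, an
    intronic tx2 that must join no region, and enough passing heterozygotes
    for a testable 5/2/5 group split with a clear parent-1 gradient.  geneB
    (span 120,000-130,000) carries tx3 with too few usable individuals per
    group to be testable.  S13 fails the 10-read rule at tx1 (9 vs 50) and
    both read filters at tx3 (3 vs 40); S14 fails only the 10%%
    minor-fraction rule at tx1 (15 vs 200).  Expected outputs live in the
    packaged ``toy_golden.json``.
    """
    samples = [f"S{i:02d}" for i in range(1, 15)]

    snps = pd.DataFrame(
        [
            {"snp_id": "rs_toy", "chrom": "chr1", "pos": 1000, "ref": "A", "alt": "G"},
            {"snp_id": "tx1", "chrom": "chr1", "pos": 6001, "ref": "T", "alt": "C"},
            {"snp_id": "tx2", "chrom": "chr1", "pos": 9501, "ref": "T", "alt": "C"},
            {"snp_id": "tx4", "chrom": "chr1", "pos": 11001, "ref": "T", "alt": "C"},
            {"snp_id": "tx3", "chrom": "chr1", "pos": 125001, "ref": "T", "alt": "C"},
        ]
    ).set_index("snp_id")

    def gt_map(pairs: dict[str, tuple[str, str]], default: tuple[str, str]):
        return [pairs.get(s, default) for s in samples]

    gt = {
        "rs_toy": gt_map(
            {"S06": ("A", "A"), "S07": ("G", "G"),
             **{s: ("G", "A") for s in ["S08", "S09", "S10", "S11", "S12", "S14"]}},
            ("A", "G"),
        ),
        "tx1": gt_map({"S03": ("C", "T"), "S09": ("C", "T")}, ("T", "C")),
        "tx2": gt_map({"S01": ("T", "C")}, ("T", "T")),
        "tx4": gt_map({"S01": ("T", "C")}, ("T", "T")),
        "tx3": gt_map(
            {"S03": ("T", "T"), "S06": ("T", "T"), "S08": ("C", "T")},
            ("T", "C"),
        ),
    }
    # only these samples carry tx3 calls that matter; the rest are hom T|T
    for s in samples:
        if s not in ("S01", "S02", "S03", "S06", "S08", "S09", "S13"):
            gt["tx3"][samples.index(s)] = ("T", "T")

    a1 = np.empty((len(samples), len(snps)), dtype=object)
    a2 = np.empty_like(a1)
    for j, sid in enumerate(snps.index):
        for i in range(len(samples)):
            a1[i, j], a2[i, j] = gt[sid][i]
    genotypes = GenotypeTable(
        samples, snps, a1, a2, np.ones(a1.shape, dtype=bool))

    tx1_counts = {
        "S01": (30, 10), "S02": (24, 16), "S03": (10, 30), "S04": (28, 12),
        "S05": (26, 14), "S06": (20, 20), "S07": (19, 21), "S08": (12, 28),
        "S09": (28, 12), "S10": (14, 26), "S11": (10, 30), "S12": (13, 27),
        "S13": (9, 50), "S14": (15, 200),
    }
    tx3_counts = {
        "S01": (20, 20), "S02": (15, 15), "S03": (35, 0), "S06": (40, 0),
        "S08": (18, 22), "S09": (30, 12), "S13": (3, 40),
    }
    rows = []
    for s, (r, a) in tx1_counts.items():
        rows.append((s, "tx1", "chr1", 6001, r, a))
    rows.append(("S01", "tx2", "chr1", 9501, 50, 50))
    rows.append(("S01", "tx4", "chr1", 11001, 18, 22))
    for s, (r, a) in tx3_counts.items():
        rows.append((s, "tx3", "chr1", 125001, r, a))
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)

    annotation = AnnotationSet(
        pd.DataFrame(
            [{"gene_id": "geneA", "chrom": "chr1", "strand": "+",
              "start": 5000, "end": 15000},
             {"gene_id": "geneB", "chrom": "chr1", "strand": "-",
              "start": 120000, "end": 130000}]
        ).set_index("gene_id"),
        {"geneA": [(5000, 9000), (10000, 15000)],
         "geneB": [(120000, 130000)]},
    )
    risk_snps = pd.DataFrame(
        [{"snp_id": "rs_toy", "chrom": "chr1", "pos": 1000, "risk_allele": "G"}]
    ).set_index("snp_id")
    covariates = pd.DataFrame(
        {"age": np.linspace(25, 77, len(samples)).round(1),
         "sex": [i % 2 for i in range(len(samples))]},
        index=pd.Index(samples, name="sample"),
    )
    expression = pd.DataFrame(
        {"geneA": np.linspace(80, 120, len(samples)).round(2),
         "geneB": np.linspace(40, 60, len(samples)).round(2)},
        index=pd.Index(samples, name="sample"),
    )
    return SimulatedCohort(genotypes, counts, annotation, risk_snps,
                           expression, covariates, truth={"fixture": "toy"})


def toy_golden() -> dict:
    """Hand-computed expected outputs for :func:`make_toy_fixture`."""
    import json
    from importlib import resources

    with resources.files("aeqtl.data").joinpath("toy_golden.json").open() as fh:
        return json.load(fh)
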