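# aeqtl — phase-aware allelic-expression QTL mapping

`aeqtl` links candidate risk SNPs (typically non-transcribed GWAS hits) to
the genes they regulate by exploiting haplotype phase. For each individual
that is heterozygous at a transcribed SNP (txSNP), RNA-seq reads reveal how
expression is split between the two parental haplotypes. If a nearby risk
SNP drives expression in *cis*, then individuals carrying the risk allele
on the parent-1 haplotype should show a parent-1 expression share above
one half, individuals carrying it on parent-2 a share below one half, and
risk-homozygous individuals a balanced share. `aeqtl` turns that idea into
a regression test:

```
fraction_P1 ~ risk-SNP group (0/1/2) + covariates
```

where `fraction_P1` is a sample's mean parent-1 read fraction over a
gene's usable txSNPs and the group codes the *phase* of the risk-SNP
genotype — designated allele on parent 1 (0), homozygous (1), designated
allele on parent 2 (2). Because each individual serves as its own control,
the approach retains power where a conventional total-expression eQTL is
washed out by between-individual variability; a matched eQTL model and a
phase-free allelic-variance test are included for comparison.

The package covers the full path from raw inputs to results: phased-VCF /
count-table / BED12-GFF3 parsing, txSNP-region construction with merging
of overlapping genes, risk-SNP pairing within a distance window, a strict
QC filter cascade, OLS model fits with PCA-derived covariates,
Benjamini–Hochberg FDR per test family, reference-mapping-bias
diagnostics, and a fully truth-tracked cohort simulator.

## Inputs

| File | Format | Contents |
| --- | --- | --- |
| genotypes | VCF (phased `GT`) | risk SNPs and txSNPs; `\|`-separated calls carry phase, `/`-separated calls are kept but refused by phase-dependent steps |
| counts | TSV | `sample, snp_id, chrom, pos, ref_count, alt_count` — allelic read counts per sample × txSNP |
| annotation | GFF3 or BED12 | gene spans plus exon/UTR intervals |
| risk SNPs | TSV | `snp_id, chrom, pos, risk_allele` |
| expression | TSV | samples × genes total-expression matrix (for the comparison eQTL) |
| covariates | TSV | per-sample table; `age` and `sex` are used, other numeric columns pass through |

All coordinates are 1-based in files and 0-based half-open internally.

## Quick start (CLI)

```
$ aeqtl simulate --out demo/sim --n-samples 120 --n-genes 3 --seed 42
wrote cohort (120 samples, 3 genes) to demo/sim

$ aeqtl run --vcf demo/sim/genotypes.vcf --counts demo/sim/counts.tsv \
    --annotation demo/sim/annotation.gff3 --risk-snps demo/sim/risk_snps.tsv \
    --expression demo/sim/expression.tsv --covariates demo/sim/covariates.tsv \
    --out demo/results
3 pairs, 3 testable, 3 gene-level aeQTLs at FDR 0.05; results in demo/results
```

`demo/results/aeqtl_gene.tsv` then contains (abridged):

```
pair_id         direction  slope    stderr   pvalue     qvalue     n_group0/1/2
rs_g1|gene0001  up         0.1112   0.0100   2.92e-18   4.38e-18   21/54/20
rs_g2|gene0002  up         0.1072   0.0086   1.56e-21   4.69e-21   27/51/24
rs_g3|gene0003  up         0.0818   0.0099   1.43e-12   1.43e-12   20/55/21
```

The simulated risk-haplotype expression share is π = 0.6, so the fitted
per-group slope of ≈ 0.1 recovers the truth (the fraction moves by
2π − 1 = 0.2 between the two heterozygous phase groups, i.e. 0.1 per group
step). Alongside it the run writes `aeqtl_txsnp.tsv` (per-txSNP fits,
separate FDR family), `eqtl.tsv` (total-expression comparison),
`bias_checks.tsv` (per-pair mapping-bias regressions — all clean here,
e.g. `rs_g1|gene0001` slope 0.0038, p 0.75), `fractions.tsv`,
`funnels.json` (where every candidate record was lost in QC) and
`manifest.json` (config snapshot, input digests, stage counts, global
reference-allele fraction 0.5031).

`aeqtl diagnose --results demo/results --out demo/diag` adds per-pair
fraction summaries for plotting.

## Quick start (Python)

```python
from aeqtl import SimConfig, simulate_cohort, run_analysis

cohort = simulate_cohort(SimConfig(n_samples=200, pi=0.6, seed=7))
result = run_analysis(cohort.genotypes, cohort.counts, cohort.annotation,
                      cohort.risk_snps, cohort.expression, cohort.covariates)
r = result.gene_results[0]
print(f"{r.pair_id}: slope {r.slope:+.4f} (SE {r.stderr:.4f}), "
      f"p = {r.pvalue:.3g}, q = {r.qvalue:.3g}, direction {r.direction}, "
      f"groups {r.group_n}")
```

prints

```
rs_g1|gene0001: slope +0.0949 (SE 0.0069), p = 6.6e-29, q = 6.6e-29, direction up, groups (40, 77, 48)
```

The model layer follows the scikit-learn estimator protocol
(`AeQTLRegressor`, `EQTLRegressor`, `InteractionRegressor`,
`AllelicVarianceTest`: `fit`, `get_params`, fitted attributes such as
`slope_`, `pvalue_`, `residuals_`), with `fit_aeqtl`-style functions as
thin wrappers.

## QC and reporting conventions

- Per sample × txSNP: heterozygous and phased, ≥ 10 reads from **each**
  allele, and the minor allele contributing ≥ 10 % of the site's reads.
  A pair is testable when ≥ 2 of the 3 phase groups have ≥ 5 usable
  individuals. All thresholds are configurable (`--min-reads`,
  `--min-minor-frac`, `--min-group-n`, config file keys).
- Risk SNPs pair with every txSNP-region whose nearest gene-span boundary
  lies within 200 kb (`--window`); overlapping gene spans are merged
  transitively into one region.
- Gene-level, txSNP-level and eQTL families are FDR-corrected separately
  (Benjamini–Hochberg, `--alpha`, default 0.05).
- `direction` is reported relative to the designated **risk allele**:
  "up" means the risk-allele haplotype carries the larger expression
  share.
- Each tested pair gets a mapping-bias check — a regression of the
  reference-allele-oriented fraction on the phase-free risk-allele dosage.
  Genuine phase effects cancel in reference orientation, so a significant
  slope flags a potential alignment-bias artifact; flags are reported,
  never auto-excluded.

## Limitations

- Fractions from multiple txSNPs of one gene reuse the same underlying
  reads when txSNPs share transcripts, so the per-gene mean is not a sum
  of independent observations; depth-related overdispersion is visible in
  the residual diagnostics (`qq_and_residual_summary`).
- Unphased heterozygous risk-SNP calls are excluded, not imputed.
- The eQTL comparison uses expression principal components as covariates;
  on very small gene panels those PCs can absorb genuine dosage effects
  (see `docs/methods.md`).
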