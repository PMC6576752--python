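# Methods

This note defines the statistical procedures implemented in `aeqtl`
precisely enough to re-derive every number the package produces.

## 1. Quantities

For sample *i*, txSNP *t* with phased heterozygous genotype, let
`(p1, p2)` be the read counts attributed to the parent-1 and parent-2
haplotypes (obtained by orienting the `(ref, alt)` counts through the
phased call). The per-site parent-1 fraction is `p1 / (p1 + p2)`.

A **txSNP-region** is the set of exonic/UTR txSNPs of one gene; genes
whose transcription spans overlap are merged transitively into a single
region so that reads spanning shared exons are never tested twice. A
sample's **fraction_P1** for a region is the *unweighted mean* of its
usable per-site fractions. The mean (rather than pooling counts) is the
default because each heterozygous txSNP is one noisy observation of the
same underlying haplotype ratio; pooling would weight sites by depth and
let one deep site dominate. Pooled summarization
(`region_summary = pooled`) is available as a sensitivity analysis.

The **risk-SNP group** codes the phase of the risk-SNP genotype with
respect to a designated allele: 0 = designated allele on parent 1,
1 = homozygous (either allele), 2 = designated allele on parent 2.
Internally the *reference* allele is designated, and results are
re-oriented to the risk allele at reporting time: when the risk allele is
the ALT allele, the slope sign is interpreted with the group order
reversed. `direction = "up"` always means "the risk-allele haplotype
carries the larger expression share."

## 2. QC filter cascade

Per (sample, txSNP) record, all of:

1. genotype heterozygous and phased (unphased heterozygotes have no
   defined parent-1 and are counted as losses, never guessed);
2. minor allele ≥ `min_reads_per_allele` (default 10) reads;
3. minor allele ≥ `min_minor_fraction` (default 10 %) of the site's
   reads — guards against genotyping errors and mono-allelic artifacts
   masquerading as strong imbalance.

A record can fail 2 and 3 simultaneously; the funnel counts both reasons
independently, so funnel columns are loss *reasons*, not a partition.
A (risk SNP, region) pair is **testable** when ≥ `min_groups` (2) of the
three groups have ≥ `min_group_n` (5) usable individuals. Every loss is
recorded per pair in `funnels.json`.

**Known property — truncation shrinkage.** Filters 2–3 clip the extreme
tails of the fraction distribution (at depth ~50 a fraction above ≈ 0.8
cannot pass the 10-read rule). Group means are therefore pulled slightly
toward 0.5: at π = 0.6, depth 50, the expected group-0 minus group-2 gap
is ≈ 0.196 rather than the unfiltered 2π − 1 = 0.2. This is a property of
the filtered estimator, not an implementation error; the hypothesis test
itself is unaffected (the shrinkage is a monotone attenuation, not a sign
or calibration change).

## 3. Pairing

A risk SNP pairs with every region on its chromosome whose nearest
gene-span boundary lies within `window` (default 200 kb). Distance is
signed: 0 inside a span, negative when the gene lies toward lower
coordinates, positive toward higher; ranks per risk SNP are assigned by
absolute distance with ties broken by region id. The implementation is
cross-checked against a brute-force per-gene scan on random layouts,
including layouts placed exactly on the window boundary.

## 4. Models

All models are ordinary least squares with a two-sided t-test on the
coefficient of interest.

- **Gene-level aeQTL**: `fraction_P1 ~ const + group + covariates`, group
  as a numeric 0/1/2 trend (a categorical two-contrast coding with a
  joint F-test is available). Under a genuine cis effect with
  risk-haplotype share π, the three group means are π, ½, 1 − π (in
  risk-designated orientation), which is exactly linear in the group
  code — the numeric trend is the natural parameterization, one
  parameter for one monotone phase effect.
- **txSNP-level aeQTL**: the same model per txSNP, with the testability
  rule re-applied per txSNP; a separate FDR family.
- **eQTL comparison**: `log2(expression + 1) ~ const + dosage +
  covariates` with the phase-free risk-allele dosage 0/1/2 on all
  genotyped samples.
- **Interaction**: `fraction ~ group * moderator + covariates` for binary
  moderators (e.g. diagnosis), reporting the interaction coefficient and
  per-stratum fits.
- **Allelic-variance test** (phase-free fallback): one-sided
  Brown–Forsythe-type two-sample t on |f − median(stratum)| comparing
  risk-heterozygous vs risk-homozygous individuals. Heterozygous
  individuals should be more *dispersed* (some have the risk allele on
  parent 1, some on parent 2) even without phase. Folding the signed
  effect into a dispersion doubles the noise floor and halves the usable
  signal, so its power collapses for weak effects while the phase-coded
  regression's does not; for strong effects both saturate.

**Covariates.** Age, sex, the top 3 genotype principal components and
the top 10 expression principal components, computed once on the full
cohort and entered identically in every fit. PCs beyond the matrix rank
are zero columns and are dropped, as is any covariate that is exactly
collinear with columns preceding it (the intercept and the tested
regressor are protected; if *they* are collinear the pair is
unidentifiable and the fit raises). Caveat: on simulated panels with only
a handful of genes, 10 expression PCs span essentially the whole
expression space and can absorb a genuine dosage effect in the eQTL
model; small-panel analyses should reduce `k_expr_pcs` or disable
covariates.

**Degenerate fits.** When the residual mean square is numerically zero
the t statistic is undefined; the package reports p = 1 for a zero slope
and the double-precision floor 2.2e-16 (as a "p < 2.2e-16"-style bound)
for a nonzero one.

**Multiple testing.** Benjamini–Hochberg step-up at α (default 0.05),
applied separately to the gene-level, txSNP-level and eQTL families; the
realized p-value cutoff (largest p called significant) is reported per
family.

## 5. Symmetries

Two exact invariances serve as self-checks, verified to ~1e-16 on
simulated batches:

- Relabeling the parent haplotypes **at the risk SNP only** maps group
  g → 2 − g while fractions are untouched: the slope negates exactly and
  the p-value is unchanged.
- Relabeling the parents at **every** SNP additionally maps f → 1 − f;
  the two transformations compose to leave slope, SE and p identical.
  Parent labels are an arbitrary bookkeeping choice, and the inference is
  exactly equivariant under it.

## 6. Mapping-bias diagnostics

Aligners favor reads matching the reference sequence, inflating the
cohort-wide reference-allele fraction at heterozygous sites above ½.
`ref_fraction_summary` reports that quantity (per-txSNP mean, then
mean ± SD over txSNPs); `compare_count_sets` compares two alignments of
the same reads (e.g. unmasked vs N-masked) by paired Wilcoxon over
per-txSNP means.

Per tested pair, `group_bias_check` regresses the
reference-allele-oriented fraction on the **phase-free** risk-allele
dosage. In reference orientation a genuine phase effect contributes
+δ or −δ depending on which parent carries the reference base, so it
cancels in expectation within each dosage stratum; a genotype-correlated
mapping bias does not cancel and produces a nonzero slope. Dosage (not
the phase group) is used deliberately: the check is invariant to parent
relabeling by construction, and bias mechanisms act on genotype, not
phase. Flags (p < 0.05) are reported next to results and never
auto-excluded. In adversarial simulations with a per-risk-allele-copy
reference shift of 0.05 — the magnitude of the weakest slopes the aeQTL
model reports as discoveries, i.e. a bias big enough to masquerade as a
finding — the flag fires in 100 % of 100 seeds, with a ~5 % false-flag
rate under genotype-independent bias (the nominal level of the test).

Residual diagnostics per fit (`qq_and_residual_summary`): normal QQ
table, per-group absolute-residual spread, and a Breusch–Pagan
heteroscedasticity score.

## 7. Simulator

Per gene: risk-SNP haplotypes drawn under Hardy–Weinberg equilibrium
(MAF `risk_maf`); txSNP haplotypes independent HWE draws (MAF
`txsnp_maf`) or coupled to the risk haplotype with probability
`coupling`. At a heterozygous txSNP, reads follow a binomial (or
beta-binomial with intra-site correlation `rho`) whose parent-1 success
probability is π, 1 − π or ½ according to the risk-SNP phase — exactly
the alternative the aeQTL model tests. Homozygous sites emit only their
own allele. An additive reference-mapping bias `bias_ref`, an optional
genotype-coupled bias `bias_genotype_coeff` (for exercising the bias
flag) and phasing switch errors `switch_error_rate` can be injected.
Total expression is multiplicative in dosage, age and sex with log-normal
noise. Depth is Poisson at `depth_mean` (negative binomial when
`depth_dispersion` > 0). Every latent quantity (haplotypes, groups,
per-site probabilities) is kept in a truth record, and a fixed seed
yields byte-identical outputs.

Default evaluation conditions — n = 300 samples, 3 txSNPs/gene, depth
50×, risk MAF 0.5, txSNP MAF 0.3, π = 0.6 — give a clearly non-null but
realistic single-gene scenario; π = 0.5 defines the null batches used for
FDR calibration.

## 8. Toy fixture

`make_toy_fixture()` ships a 14-sample, 2-gene dataset exercising the
read-filter and testability branches: a record failing only the 10-read
rule, one failing only the minor-fraction rule, one failing both, an
intronic txSNP that joins no region, a testable 5/2/5 pair and an
untestable 2/0/2 pair. All expected outputs were computed by hand
and live in `aeqtl/data/toy_golden.json`; the pipeline must reproduce
them exactly, which pins the coordinate conventions, the filter
semantics and the funnel accounting.
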