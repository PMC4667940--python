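# Methods

## The analysis

The pipeline tests, for a curated set of SNP-miRNA pairs, whether
miRNA expression varies linearly with the additive genotype code, whether
the tumor-minus-normal expression difference varies with genotype, and
whether the same SNPs are associated with case status. It is organized in
three statistical stages after preprocessing and filtering.

### Normalization

Microarray total gene signal is made comparable across samples by the
75th-percentile scaling factor, stratified by tumor site:

    f_j = median_{k in stratum(j)}(q75_k) / q75_j,      x'_ij = f_j · x_ij

with percentiles computed by linear interpolation between order
statistics (the common statistical default; the percentile convention is
recorded in the normalization report because upstream array software does
not pin it). After scaling, every sample's 75th percentile equals its
stratum's median pre-scaling 75th percentile exactly (the fixed point),
and a second pass is the identity. Two consequences worth knowing:
rescaling one sample's raw signal cancels out of its normalized values
(as long as the stratum median is unmoved), while rescaling an entire
stratum by c rescales that stratum's normalized values by c — the fixed
point target itself scales.

Strata default to tumor site (proximal/distal) applied separately within
the tumor and the non-tumor sample sets; whether the original analyses
pooled tissues within a site is not documented, so both behaviors are
supported (`strata_mode`).

Tests run on `log2(signal + offset)` with offset 1.0 by default; result
tables report means on the normalized, non-log2 scale, which is the
convention of the field's published tables (zero signals make a positive
offset unavoidable). The `% 0 Exp` descriptor is `100·(1 − prevalence)`
where prevalence is the proportion of samples with signal > 0.

### Pair expansion and filtering

Curated pair lists often carry generic miRNA names that predate the
arm-specific (-5p/-3p) delineation. A generic name is expanded to every
platform name sharing its family token; a letter variant, locus number or
arm present in the input restricts matches to that component. The exact
rule used by the original studies is not documented; this declared
convention reproduces the canonical let-7 worked example (one generic
name → every lettered/arm variant on the platform) and is validated only
at that granularity.

The cascade then applies four ordered filters (expression anywhere,
genotype availability, polymorphism + exact Hardy-Weinberg test,
non-tumor expression prevalence ≥ 5%), attributing each dropped pair to
the first stage it fails so that per-stage drops plus survivors always
sum to the input count. "Did not have variation" is operationalized as
fewer than 2 minor-allele carriers (configurable; no published threshold
exists). The HWE test is the exact conditional test: all heterozygote
counts compatible with the observed allele counts are enumerated and the
two-sided p sums the probabilities of configurations no more likely than
the observed one. The threshold default is 1e-4, the conventional GWAS QC
level. Array-level QC (GenTrain scores, duplicate concordance, Mendelian
errors) requires raw intensity/pedigree data and is represented only as
an optional pre-supplied SNP exclusion list.

### Trend tests with bootstrap p-values

Stage 1 regresses log2 non-tumor expression on the genotype code with age
(continuous), sex and center (one-hot, reference level) by OLS; the
genotype coefficient β is the per-minor-allele log2 change. Significance
uses a nonparametric case-resampling bootstrap: rows (outcome, genotype,
covariates together) are resampled with replacement B times (default
10,000), the model refit, and

    p = 2 · min(#{β* ≤ 0} + 1, #{β* ≥ 0} + 1) / (B + 1),  capped at 1.

The add-one convention keeps p strictly positive; the attainable minimum
is 2/(B+1). Replicates with a degenerate resampled genotype (one distinct
value) are redrawn; if more than half of the first draw is degenerate the
test aborts with advice to filter monomorphic SNPs. Case resampling was
chosen because it is the generic published description of the procedure;
a residual bootstrap is available behind `BootstrapSpec(method=
"residual")` for sensitivity analysis. With Gaussian errors the bootstrap
p agrees with the classical OLS t-test p up to Monte-Carlo error, which
the acceptance study measures directly.

Stage 2 applies the same machinery to the paired difference d_i =
log2 tumor_i − log2 normal_i (individuals missing either tissue dropped
with a logged count), and separately runs a paired t-test per miRNA with
a bootstrap null: differences are mean-centered, resampled with
replacement, and p = (#{|t*| ≥ |t_obs|} + 1)/(B + 1). Zero-variance
differences yield p = 1 with a degenerate flag.

Raw p-values are reported alongside Benjamini-Hochberg adjusted values;
the FDR family is all pairs tested within each analysis in the run,
matching the published practice of adjusting over the full set of tested
comparisons.

### Risk models

Case/control status is modeled by logistic regression with the genotype
entered as heterozygote and rare-homozygote indicators against the
common-homozygote referent, adjusted for age, sex and center; a
per-allele trend model is available. The fit is maximum likelihood via
IRLS with step-halving (each recorded deviance is no larger than the
previous one), converging when the relative log-likelihood change drops
below 1e-8, capped at 50 iterations. Odds ratios are exp(coefficient)
with Wald 95% intervals; complete separation (a diverging coefficient or
fitted probabilities at 0/1) is flagged and the affected interval
suppressed. Without covariates the indicator model is saturated and its
ORs coincide with the crude 2×2 ORs — an identity the tests check to six
significant digits. Crude ORs use the Woolf log interval with the
Haldane-Anscombe +0.5 correction when any cell is zero; a genotype class
with no observations at all is reported as undefined, mirroring the blank
cells of published risk tables.

## The synthetic generator

`SyntheticConfig` defaults describe a cohort shaped like the paired-tissue
study the pipeline targets: 344 individuals; ages Normal(65, 9.5)
truncated to [30, 79]; two study centers; a per-individual tumor site
(proximal/distal) used as the normalization stratum; minor allele
frequencies uniform on (0.05, 0.5] with HWE genotypes; per-miRNA log2
intercepts uniform on (3, 10), matching the orders of magnitude of
published signal tables (means from below 1 to several thousand);
residual SD sigma = 1.0 on the log2 scale; hurdle zero probability
pi_zero = 0.2 (published `% 0 Exp` columns span 0-90%, with many rows in
the tens); tumor shift delta_tumor = 1.0 (a twofold change, the scale of
published tumor/normal differences); genotype effect beta_g = 0.5 and
interaction gamma_gxt = 0 by default — the magnitude of real genotype
effects on miRNA expression is not published, so the default is chosen
for test power, not realism; risk odds ratio 1.3 per minor allele on one
designated causal SNP (the scale of the published significant risk
associations, 1.2-2.3). Zeros are injected independently of the latent
value (a hurdle), keeping the generating effects interpretable and
matching the practice of reporting `% 0 Exp` as a separate descriptor;
case status is balanced by centering the logistic linear predictor,
mirroring a case-control design.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, imputation uncertainty, array-level technical artifacts (spatial,
batch, probe effects), correlation between miRNAs, and within-individual
correlation of tumor and normal residuals. Passing tests therefore show
the machinery is correct and calibrated under the stated model, not that
the model captures every feature of real microarray data.

## Numerical choices and study sizes

- Bootstrap refits solve the batched normal equations for all replicates
  at once; singular replicates fall back to a pseudo-inverse.
- Seeded runs are bit-reproducible end to end; the pipeline derives
  per-pair bootstrap seeds from the run seed via `SeedSequence`.
- Calibration studies in the test suite and acceptance script use scaled
  problem sizes chosen as adequate for their Monte-Carlo tolerances:
  1,000 null datasets (n = 300, B = 500) for the size study, 100 Gaussian
  datasets (n = 500, B = 1,000) for bootstrap/t-test agreement, 200
  replicates at n = 1,000 for 95%-CI coverage of the generating
  parameters, 10 full-pipeline runs for planted-signal recovery.
- Recovery and planted-signal studies set pi_zero = 0: a hurdle zero
  enters the regression as log2(offset) ≈ 0, an outlier of magnitude
  comparable to the miRNA's intercept, so under zero-inflation the OLS
  trend estimate is attenuated toward zero. These studies certify the
  estimator under the generative linear model; the attenuation under the
  hurdle is the expected behavior of the published method, not a defect
  of the implementation.

## Known limitations

- The trend test treats genotype as numeric 0/1/2; dominance patterns are
  visible only through the genotype-class descriptives.
- Zero-inflated miRNAs (large `% 0 Exp`) attenuate the linear trend; a
  two-part (hurdle) test is out of scope.
- The bootstrap p has granularity 2/(B+1); FDR-adjusted values computed
  from many such p-values inherit it.
- HWE is tested on all genotyped individuals as provided (cases plus
  controls) unless the caller pre-subsets; the original QC context
  (GWAS-panel QC before the eQTL analysis) is not reconstructable here.
- The published study-flow counts (559 → 835 → 622 → 552 → 548 → 327
  pairs) depend on unreleased individual-level data and are not
  reproduction targets; the cascade is validated against planted-failure
  fixtures with an independent per-record audit instead.
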