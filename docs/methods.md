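# Methods

## Allelic expression imbalance (AEI)

For a subject heterozygous at a transcribed marker SNP, each assay
replicate reports the major/minor allele peak ratio in cDNA; genomic DNA
from the same subject is assayed identically. AEI is quantified as

- `norm_ratio = mean(cDNA replicates) / mean(gDNA replicates)` —
  arithmetic means by default, because assay replicate SDs are conventionally
  reported on the linear ratio scale; geometric aggregation is available as
  a switch for strongly skewed replicates;
- `folded_ratio = max(norm_ratio, 1/norm_ratio)` — the direction of
  imbalance is uninformative when the marker is not in LD with the causal
  variant, so only the magnitude is kept.

### Thresholds and categories

The presence threshold is `1 + 3·SD` of replicate cDNA ratios around unity
(`derive_threshold`). The center is fixed at 1.0 — gDNA normalization puts
null ratios at unity, and centering on the cohort mean would absorb real
imbalance. With replicate SDs of 0.12–0.13 this gives ≈1.36–1.39; the
package defaults to `t_moderate = 1.4` and `t_high = 2.0`. Category 1
includes both boundaries (`t_moderate ≤ r ≤ 2`); category 2 is strictly
`> 2`. Explicit thresholds can be supplied to match any published pair
(assay SDs are rarely reported precisely enough to re-derive them exactly).

Subjects measured at two markers are reconciled: agreement keeps the
category, discordance is called moderate (category 1). Subjects homozygous
at every marker are absent from the AEI table — imbalance is unobservable
for them, not zero — and are excluded from scanning rather than treated as
category 0.

### Copy-number screening

A mean gDNA folded ratio above `1 + 3·SD_gDNA` flags possible copy-number
variation; flagged subjects are dropped from scanning with a logged
warning. The tolerance uses the *assay-level* gDNA replicate SD (pooled
across subjects per marker), not a single subject's replicate SD, which is
far too unstable at 2–3 replicates. The boundary itself passes.

## Candidate-SNP scan

Genotypes are recoded het (dosage 1) vs hom (0 or 2): a cis effect is only
observable in heterozygous carriers, making heterozygosity itself the
natural predictor regardless of which allele is functional. Per SNP, a
one-way ANOVA F-test (equivalently the squared pooled-variance t) compares
the AEI response between classes. The default response is the ordinal
category 0/1/2 treated as numeric — matching the screening convention of
testing AEI *status* — with the continuous folded ratio available as a
switch. Bonferroni correction multiplies by the number of SNPs attempted
(including untestable ones) and clips at 1. Missing genotypes are deleted
pairwise per SNP; a SNP needs ≥ 2 subjects per class to be testable, and a
constant response yields F = 0, p = 1 by convention.

Note that a fully null cohort has an almost surely constant category
response (noise essentially never crosses a 3·SD threshold), so null
p-values under the category response are a point mass at 1; the uniformity
of null p-values is a property of the continuous-response scan, and is
tested there.

## Exact r×c test (Freeman–Halton)

Conditional on both margins, a table has multivariate hypergeometric
probability `∏ r_i! ∏ c_j! / (n! ∏ x_ij!)`. The two-sided p is the total
probability of tables no more probable than the observed one — the
probability-mass convention, which for 2×2 reduces to the classical
two-sided Fisher test. Conventions that instead double one tail exist and
can differ; the probability-mass definition is the standard r×c choice.
Probabilities are computed in log space from `gammaln`, and ties are
accepted within a relative tolerance of 1e-7 so floating-point rounding
cannot drop an exactly tied table. Enumeration is depth-first over cells
with forced last row/column; a guard aborts above 2×10⁷ tables and points
to the Monte-Carlo estimator, which samples tables by seeded random
re-pairing of row and column labels and uses the add-one estimator
`(k+1)/(B+1)`. Tables with a zero margin (or fewer than two rows/columns)
are degenerate: p = 1 with a warning.

## Genetic-model association statistics

- **Collapses.** Allelic: minor vs major allele counts (2 per subject);
  dominant: carriers vs non-carriers; recessive: minor homozygotes vs rest.
  Each 2×2 gets Pearson chi-squared (no continuity correction — the
  convention that reproduces published values), the exact Fisher p, and the
  Woolf odds-ratio CI `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`. Zero cells
  take the Haldane–Anscombe +0.5 correction with a warning.
- **Additive.** Cochran–Armitage trend test with scores (0, 1, 2), score
  variant `U²/Var(U)` with `Var(U) = p̄(1−p̄)[Σs²N_j − (ΣsN_j)²/N]`. The
  trend statistic coincides with the allelic chi-squared exactly when the
  *pooled* genotype counts sit on Hardy–Weinberg proportions (arms each in
  HWE at different frequencies do **not** satisfy this — the pooled mixture
  is out of HWE); the property test asserts the pooled condition.
- **Count reconstruction.** Published MAF/n pairs are converted to allele
  counts by nearest-integer rounding (ties to even) of `2n·MAF`, warning
  when the round trip misses the printed precision. Dominant/recessive
  tests are *not* derivable from MAFs alone (they need genotype counts, and
  assuming HWE demonstrably fails to reproduce published dominant and
  recessive odds ratios), so MAF-only input enables the allelic model only.
- **HWE.** Exact conditional test: enumeration of all heterozygote counts
  with the parity of the observed minor-allele count,
  probability-mass two-sided p. Monomorphic input returns p = 1.
- **Covariates.** Sex and age are handled by stratified re-analysis
  (`maf_by_stratum`, per-stratum `model_test` runs), not covariate-adjusted
  regression — matching how stratified results are reported in this kind of
  follow-up and keeping every statistic exact.
- **Count traits.** Pearson correlation of dosage with the count trait,
  p from the t transform on n−2 df. (Spearman would be a defensible
  alternative; Pearson on dosage is the stated default.)

## Synthetic cohort generator

The generator reproduces the structure the analysis assumes, at assay
granularity only (no reads, probes or isoform mixtures).

- **Haplotypes.** Each LD pair couples one SNP to an anchor (the causal
  variant when present) through the positive-D two-locus haplotype
  frequencies implied by (MAF, MAF, r²): `D = √(r²·p(1−p)q(1−q))`,
  `f₁₁ = pq + D`. Feasibility is checked against
  `D_max = min(p(1−q), (1−p)q)` and violations report the maximum feasible
  r². All other SNPs segregate independently; multi-locus haplotype
  copulas are out of scope because the analysis only needs marker–causal
  and candidate–causal LD.
- **Cis effect.** Heterozygous carriers of the causal variant express AEI
  with diagnosis-specific penetrance; the fold change is `exp(|N(μ, σ)|)`,
  folded so every expressed effect is ≥ 1 before phase assignment. The
  haplotype carrying the causal minor allele is scaled by the fold, and the
  observable ratio at each heterozygous marker follows from the *sampled*
  phase — fold or reciprocal depending on which marker allele is in cis.
  This, not an independent coin flip, is what produces observed ratios on
  both sides of unity when marker–causal LD is low.
- **Noise.** Multiplicative log-normal (ratios stay positive), with σ_log
  solved from `SD(e^{σZ}) = sd` so the linear-scale replicate SD at a true
  ratio of 1 equals the configured assay SD exactly:
  `σ = √ln((1 + √(1+4·sd²))/2)`.
- **Phenotypes.** Binary trait:
  `logit p = logit(baseline) + ln(OR)·g(model, dosage)`; count trait:
  Poisson with `log rate = ln(base) + slope·dosage`. The driving SNP
  defaults to the causal variant (`PhenotypeModel.snp_id` overrides). Sex
  and age are independent covariates used only for stratification.
- **Default study conditions** (`stanley_config`): 3 diagnosis groups × 35
  subjects; marker SNPs at MAF 0.32 and 0.20 (matching observed
  heterozygote fractions of ~44% and ~31%) with assay SDs 0.12/0.13 (cDNA)
  and 0.06/0.05 (gDNA), 3 cDNA + 2 gDNA replicates; causal variant at MAF
  0.181 with marker LD r² = 0.003 and 0.044; 12 further candidates at their
  observed MAFs in linkage equilibrium with the causal SNP. The cis effect
  uses fold-change log-mean ln 3 and log-sd 0.5 — putting most expressed
  folds between ~2 and ~8 with occasional values above 10, the reported
  range — with penetrance 0.8 in both disease groups and 0 in controls.
  The disease-restricted penetrance is a deliberate simplification of the
  qualitative pattern (large imbalances were observed essentially only in
  disease); the magnitude of any control effect is not quantified anywhere
  and is therefore set to zero rather than guessed.
- **Determinism.** One `numpy` Generator seeded from the config drives all
  stages in fixed order; identical configs give byte-identical tables.

### What the simulator does not emulate

Real brain-bank data have batch effects, RNA-quality gradients, isoform
mixtures that can make two markers report genuinely different ratios,
cryptic relatedness, and LD among candidate SNPs. Passing
parameter-recovery tests on this generator shows the *statistics* behave
as designed under the stated model — it does not certify performance on
real tissue data.

## Problem sizes and numerical choices

Simulation-based checks use 100 seeds per arm (recovery and null
calibration), 1000 replicates for CI coverage, 500 permutations/replicates
for uniformity checks — sizes at which the binomial error of the checked
proportions is a small fraction of the acceptance bands. Exact-test
enumeration is exercised exhaustively on all 2×2 tables with total ≤ 30
against an independent hypergeometric oracle. Tolerances: enumeration
normalization to 1e-9; tie acceptance 1e-7 relative; published values are
asserted at their printed precision (one value, an upper CI bound printing
as 1.61 against a published 1.60, is allowed one rounding step — the
published rounding is not reproducible from integer counts).

## Known limitations

- Exact enumeration cost grows quickly with margins; beyond the guard rail
  only the Monte-Carlo estimate is available.
- The VCF reader handles biallelic SNPs with plain GT fields only;
  multi-allelic records are skipped with a warning.
- No covariate-adjusted regression, haplotype phasing, imputation, or
  meta-analysis; stratification is the only covariate mechanism.
- The het/hom scan cannot distinguish the causal variant from a perfect LD
  proxy; the simulator's default panel has no such proxy, real panels may.
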