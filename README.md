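# aeiscan

Mapping cis-acting regulatory variants through allelic expression imbalance
(AEI), with the exact and genetic-model association statistics used in
candidate-SNP follow-up studies.

## The problem

When one allele of a gene produces more mRNA than the other in the same
cell, the cause must act *in cis* — a regulatory DNA variant on that
chromosome copy. A transcribed heterozygous **marker SNP** lets the two
alleles' transcripts be distinguished: replicate cDNA allele-peak ratios,
normalized to the same subject's genomic DNA ratio (which is 1:1 absent
copy-number changes), estimate the allelic expression ratio. Because the
marker is usually not itself causal and may be unlinked to the causal
variant, the direction of imbalance is arbitrary, so ratios are **folded**
(high-expressing over low-expressing allele, always ≥ 1):

```
norm = mean(cDNA ratios) / mean(gDNA ratios),   folded = max(norm, 1/norm)
```

Folded ratios are classified as no AEI (< t_mod), moderate AEI
(t_mod ≤ r ≤ 2) or high AEI (> 2), with t_mod = 1 + 3·SD of replicate cDNA
ratios (≈1.4 for a replicate SD of 0.12–0.13). A *causal* cis variant
reveals itself through genotype: only heterozygous carriers can show AEI.
The scan therefore recodes each candidate SNP as het vs hom and compares
AEI between the classes with a one-way ANOVA F-test, Bonferroni-corrected
for the number of SNPs tested.

The package provides:

- `aeiscan.aei_quant` — normalization, folding, thresholds, 3-level
  classification, dual-marker reconciliation, gDNA copy-number screening;
- `aeiscan.aei_scan` — het/hom recoding, the F-test scan, category-by-group
  tables;
- `aeiscan.exact_stats` — Fisher's exact test for r×c tables
  (Freeman–Halton, full enumeration over fixed margins in log space, with a
  seeded Monte-Carlo fallback) and Pearson chi-squared;
- `aeiscan.assoc_models` — allele-count reconstruction from published
  MAF/n pairs, allelic/dominant/recessive collapses, the Cochran–Armitage
  trend test, Woolf odds-ratio confidence intervals, an exact
  Hardy–Weinberg test, dosage–count-trait correlation, per-stratum MAFs;
- `aeiscan.sim_cohort` — a fully seeded synthetic-cohort generator
  (haplotypes under pairwise LD, diagnosis-dependent cis effects, replicate
  assay noise, genotype-linked phenotypes);
- `aei-scan` — a CLI over all of the above
  (`simulate | quantify-aei | scan | assoc | assoc-from-maf | exact-test | run`).

## Worked example

```python
from aeiscan import (fisher_exact, reconstruct_allele_counts, odds_ratio_woolf,
                     quantify, scan, simulate_cohort, stanley_config, GenotypeMatrix)

# 1. Is high AEI associated with diagnosis?  Counts: 1/24 controls vs 7/26
#    bipolar subjects with a >2-fold allelic imbalance.
fisher_exact([[1, 23], [7, 19]]).p_two_sided     # -> 0.0504

# 2. Case-control follow-up from published MAFs: 12% (n=511) vs 17% (n=507)
t = reconstruct_allele_counts(0.12, 511, 0.17, 507)  # -> 123/899 vs 172/842 alleles
odds_ratio_woolf(t)                              # -> (0.67, 0.52, 0.86)

# 3. Full synthetic pipeline: simulate a 105-subject cohort, quantify AEI,
#    scan 13 candidate SNPs.
tables = simulate_cohort(stanley_config(seed=7))
aei, subjects = quantify(tables.measurements)
cand = [s for s in tables.genotypes.snp_ids
        if tables.genotypes.metadata["role"][s] != "marker"]
result = scan(GenotypeMatrix(tables.genotypes.dosage[cand]), subjects)
print(result.head(3))
```

The scan output ranks the simulated causal variant first:

```
   snp_id      maf  n_used  n_het    f_stat    p_raw   p_bonf  testable
rs2144025 0.176923      65     21 22.952866 0.000010 0.000136      True
rs2234693 0.569231      65     38  4.431102 0.039284 0.510688      True
rs2071454 0.146154      65     17  2.978182 0.089296 1.000000      True
```

`p_raw` is the two-class ANOVA p for AEI category by het/hom status;
`p_bonf` multiplies it by the 13 SNPs attempted. Only the causal variant
survives correction — heterozygous carriers are the subjects with moderate
and high AEI, while every other SNP's het/hom split is unrelated to the
imbalance.

The same pipeline runs from the shell:

```sh
aei-scan run --seed 7 --out out/          # writes aei.tsv, scan.tsv, manifest.json
aei-scan exact-test --table "17,6,1;10,9,7"
```

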