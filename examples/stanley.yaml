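groups:
- diagnosis: control
  n: 35
- diagnosis: bipolar
  n: 35
- diagnosis: schizophrenia
  n: 35
snp_panel:
- snp_id: rs3798577
  maf: 0.32
  role: marker
- snp_id: rs1801132
  maf: 0.2
  role: marker
- snp_id: rs2144025
  maf: 0.181
  role: causal
- snp_id: rs851984
  maf: 0.385
  role: candidate
- snp_id: rs1285057
  maf: 0.374
  role: candidate
- snp_id: rs543650
  maf: 0.374
  role: candidate
- snp_id: rs488133
  maf: 0.312
  role: candidate
- snp_id: rs2071454
  maf: 0.122
  role: candidate
- snp_id: rs71685044
  maf: 0.456
  role: candidate
- snp_id: rs2077647
  maf: 0.5
  role: candidate
- snp_id: rs2234693
  maf: 0.49
  role: candidate
- snp_id: rs9340799
  maf: 0.361
  role: candidate
- snp_id: rs988328
  maf: 0.147
  role: candidate
- snp_id: rs3020327
  maf: 0.109
  role: candidate
- snp_id: rs3020329
  maf: 0.276
  role: candidate
ld:
- snp_pair:
  - rs2144025
  - rs3798577
  r2: 0.003
- snp_pair:
  - rs2144025
  - rs1801132
  r2: 0.044
effect:
  causal_snp_id: rs2144025
  fold_change_log_mean_by_state:
    control: 1.0986122886681098
    bipolar: 1.0986122886681098
    schizophrenia: 1.0986122886681098
  fold_change_log_sd_by_state:
    control: 0.5
    bipolar: 0.5
    schizophrenia: 0.5
  penetrance_by_state:
    control: 0.0
    bipolar: 0.8
    schizophrenia: 0.8
noise:
  cdna_sd_by_marker:
    rs3798577: 0.12
    rs1801132: 0.13
  gdna_sd_by_marker:
    rs3798577: 0.06
    rs1801132: 0.05
  n_replicates_cdna: 3
  n_replicates_gdna: 2
phenotype:
  baseline_prevalence: 0.15
  model: dominant
  odds_ratio_per_unit: 2.7
  count_trait_rate_base: 4.0
  count_trait_log_rate_per_allele: 0.3
  snp_id: null
  female_fraction: 0.5
  age_range:
  - 18
  - 65
seed: 0
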