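"""Synthetic cohorts for allelic-expression-imbalance mapping.

The generator reproduces the statistical structure the analysis assumes,
at assay granularity (no reads or probe intensities):

* diploid haplotypes over a SNP panel, with specified minor-allele
  frequencies and pairwise r-squared linkage disequilibrium between each
  SNP and a designated anchor (normally the causal variant);
* a cis-acting causal variant: heterozygous carriers express, with a
  diagnosis-dependent penetrance, an allelic fold change drawn from a
  diagnosis-specific log-normal; the *observable* ratio at a transcribed
  marker SNP is the fold change or its reciprocal depending on which marker
  allele shares a haplotype with the causal allele — which is why observed
  ratios scatter on both sides of unity when marker and causal variant are
  in low LD;
* replicate allelic measurements with multiplicative log-normal noise
  calibrated so the linear-scale SD of replicates around a true ratio of 1
  equals the configured assay SD, plus genomic-DNA replicates centred at 1;
* genotype-linked phenotypes: a binary trait with a configurable genetic
  model and odds ratio, and a Poisson count trait with a per-allele
  log-rate slope, alongside independent sex and age covariates.

A single integer seed fully determines every output table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aei_scan import GenotypeMatrix

__all__ = [
    "SnpSpec",
    "LdSpec",
    "EffectModel",
    "NoiseModel",
    "PhenotypeModel",
    "CohortSimConfig",
    "ConfigError",
    "r2_max",
    "generate_haplotypes",
    "assign_allelic_expression",
    "simulate_measurements",
    "generate_phenotypes",
    "simulate_cohort",
    "stanley_config",
    "CohortTables",
]


class ConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    maf: float
    role: str = "candidate"  # marker | candidate | causal

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ConfigError(f"{self.snp_id}: MAF must lie in (0, 0.5]")
        if self.role not in ("marker", "candidate", "causal"):
            raise ConfigError(f"{self.snp_id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class LdSpec:
    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ConfigError("r2 must lie in [0, 1]")
        if self.snp_a == self.snp_b:
            raise ConfigError("LD pair must name two distinct SNPs")


@dataclass
class EffectModel:
    """Cis effect of the causal variant on allelic expression.

    Heterozygous carriers express AEI with probability
    ``penetrance_by_state[diagnosis]``; when they do, the fold change is
    ``exp(|N(log_mean, log_sd)|)`` (folded so every expressed effect is a
    fold >= 1 before phase assignment).  Homozygotes have no cis imbalance.
    """

    causal_snp_id: str
    fold_change_log_mean_by_state: dict[str, float]
    fold_change_log_sd_by_state: dict[str, float]
    penetrance_by_state: dict[str, float]

    def __post_init__(self) -> None:
        for state, pen in self.penetrance_by_state.items():
            if not 0.0 <= pen <= 1.0:
                raise ConfigError(f"penetrance for {state!r} must lie in [0, 1]")
        for state, sd in self.fold_change_log_sd_by_state.items():
            if sd < 0:
                raise ConfigError(f"log-sd for {state!r} must be >= 0")


@dataclass
class NoiseModel:
    cdna_sd_by_marker: dict[str, float]
    gdna_sd_by_marker: dict[str, float]
    n_replicates_cdna: int = 3
    n_replicates_gdna: int = 2

    def __post_init__(self) -> None:
        if self.n_replicates_cdna < 3:
            raise ConfigError("cDNA must be measured at least three times")
        if self.n_replicates_gdna < 1:
            raise ConfigError("need at least one gDNA replicate")
        for d in (self.cdna_sd_by_marker, self.gdna_sd_by_marker):
            for marker, sd in d.items():
                if sd < 0:
                    raise ConfigError(f"noise SD for {marker} must be >= 0")


@dataclass
class PhenotypeModel:
    """Genotype-linked binary and count traits plus covariates.

    The binary trait is Bernoulli with
    ``logit p = logit(baseline_prevalence) + ln(odds_ratio_per_unit) * g``
    where ``g`` is the model-coded genotype (dominant: carrier indicator;
    recessive: minor-homozygote indicator; additive/allelic: dosage).  The
    count trait is Poisson with
    ``log rate = ln(count_trait_rate_base) + count_trait_log_rate_per_allele * dosage``.
    """

    baseline_prevalence: float = 0.15
    model: str = "dominant"
    odds_ratio_per_unit: float = 2.7
    count_trait_rate_base: float = 4.0
    count_trait_log_rate_per_allele: float = 0.3
    snp_id: str | None = None  # defaults to the causal SNP
    female_fraction: float = 0.5
    age_range: tuple[int, int] = (18, 65)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ConfigError("baseline prevalence must lie in (0, 1)")
        if self.model not in ("allelic", "dominant", "recessive", "additive"):
            raise ConfigError(f"unknown genetic model {self.model!r}")
        if self.odds_ratio_per_unit <= 0 or self.count_trait_rate_base <= 0:
            raise ConfigError("odds ratio and base rate must be > 0")


@dataclass
class CohortSimConfig:
    groups: list[tuple[str, int]]
    snp_panel: list[SnpSpec]
    ld: list[LdSpec]
    effect: EffectModel
    noise: NoiseModel
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(n for _, n in self.groups) < 1:
            raise ConfigError("total cohort size must be >= 1")
        ids = [s.snp_id for s in self.snp_panel]
        if len(set(ids)) != len(ids):
            raise ConfigError("snp_id values must be unique within the panel")


def r2_max(p: float, q: float) -> float:
    """Largest r-squared achievable with positive D for minor MAFs p and q."""
    d_max = min(p * (1 - q), (1 - p) * q)
    return d_max**2 / (p * (1 - p) * q * (1 - q))


def _conditional_probs(p_anchor: float, p_other: float, r2: float, pair: str):
    """P(other minor | anchor allele) for the positive-D two-locus haplotype."""
    cap = r2_max(p_anchor, p_other)
    if r2 > cap + 1e-12:
        raise ConfigError(
            f"LD pair {pair}: requested r2={r2} exceeds the maximum feasible "
            f"r2={cap:.4f} for MAFs {p_anchor}/{p_other}"
        )
    d = math.sqrt(r2 * p_anchor * (1 - p_anchor) * p_other * (1 - p_other))
    f11 = p_anchor * p_other + d
    return f11 / p_anchor, (p_other - f11) / (1 - p_anchor)


def generate_haplotypes(
    panel: Sequence[SnpSpec],
    ld: Sequence[LdSpec],
    n_subjects: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample phased diploid genotypes: array (n_subjects, 2, n_snps) of 0/1.

    Entry 1 marks the minor allele.  Each LD pair couples one SNP to an
    anchor — the causal SNP when it is in the pair, else the pair's first
    SNP — via the positive-D two-locus haplotype frequencies implied by
    (MAF, MAF, r2); all other SNPs segregate independently.  A SNP may be
    coupled to at most one anchor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [s.snp_id for s in panel]
    idx = {sid: k for k, sid in enumerate(ids)}
    maf = {s.snp_id: s.maf for s in panel}
    causal = next((s.snp_id for s in panel if s.role == "causal"), None)

    dependents: dict[str, tuple[str, float]] = {}
    for spec in ld:
        for sid in (spec.snp_a, spec.snp_b):
            if sid not in idx:
                raise ConfigError(f"LD pair names unknown SNP {sid!r}")
        if causal == spec.snp_b:
            anchor, other = spec.snp_b, spec.snp_a
        else:
            anchor, other = spec.snp_a, spec.snp_b
        if other in dependents:
            raise ConfigError(f"SNP {other} appears in more than one LD pair")
        if other == causal:
            raise ConfigError("the causal SNP can only act as LD anchor")
        dependents[other] = (anchor, spec.r2)
    for other, (anchor, _) in dependents.items():
        if anchor in dependents:
            raise ConfigError(f"LD anchor {anchor} is itself coupled to another SNP")

    n_hap = 2 * n_subjects
    haps = np.empty((n_hap, len(ids)), dtype=np.int8)
    for sid in ids:
        if sid in dependents:
            continue
        haps[:, idx[sid]] = rng.random(n_hap) < maf[sid]
    for other, (anchor, r2) in dependents.items():
        p1, p0 = _conditional_probs(maf[anchor], maf[other], r2, f"{anchor}/{other}")
        a = haps[:, idx[anchor]]
        cond = np.where(a == 1, p1, p0)
        haps[:, idx[other]] = rng.random(n_hap) < cond
    return haps.reshape(n_subjects, 2, len(ids))


def assign_allelic_expression(
    haplotypes: np.ndarray,
    panel: Sequence[SnpSpec],
    effect: EffectModel,
    diagnosis: Sequence[str],
    subject_ids: Sequence[str],
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True allelic ratios at each marker, signed by haplotype phase.

    Returns ``(true_ratios, truth)``: the former has one row per
    marker-heterozygous subject and marker (subject_id, marker_id,
    true_ratio); the latter one row per subject with the causal dosage,
    whether an effect was expressed, and the (folded) fold change.
    Subjects homozygous at the causal SNP carry fold 1; heterozygotes
    express a folded log-normal fold with state-specific penetrance.  The
    observable marker ratio (major over minor marker allele) is the fold
    or its reciprocal according to whether the causal minor allele lies in
    cis with the marker's major or minor allele.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [s.snp_id for s in panel]
    idx = {sid: k for k, sid in enumerate(ids)}
    if effect.causal_snp_id not in idx:
        raise ConfigError(f"causal SNP {effect.causal_snp_id!r} not in panel")
    markers = [s.snp_id for s in panel if s.role == "marker"]
    diagnosis = list(diagnosis)
    for dx in set(diagnosis):
        if dx not in effect.penetrance_by_state:
            raise ConfigError(f"no penetrance configured for diagnosis {dx!r}")
        if dx not in effect.fold_change_log_mean_by_state:
            raise ConfigError(f"no fold-change model for diagnosis {dx!r}")

    n = haplotypes.shape[0]
    ci = idx[effect.causal_snp_id]
    causal = haplotypes[:, :, ci]  # (n, 2)
    het_causal = causal.sum(axis=1) == 1

    pen = np.array([effect.penetrance_by_state[dx] for dx in diagnosis])
    mu = np.array([effect.fold_change_log_mean_by_state[dx] for dx in diagnosis])
    sd = np.array([effect.fold_change_log_sd_by_state[dx] for dx in diagnosis])
    # fixed draw order keeps the stream reproducible regardless of genotypes
    expressed = (rng.random(n) < pen) & het_causal
    log_fold = np.abs(rng.normal(mu, sd))
    fold = np.where(expressed, np.exp(log_fold), 1.0)

    rows = []
    for s in range(n):
        if fold[s] != 1.0:
            # haplotype carrying the causal minor allele is scaled by the fold
            hap_expr = np.where(causal[s] == 1, fold[s], 1.0)
        else:
            hap_expr = np.ones(2)
        for m in markers:
            alleles = haplotypes[s, :, idx[m]]
            if alleles.sum() != 1:
                continue  # homozygous marker: alleles indistinguishable
            major_hap = int(np.argmin(alleles))  # allele 0 = major
            minor_hap = 1 - major_hap
            rows.append(
                {
                    "subject_id": subject_ids[s],
                    "marker_id": m,
                    "true_ratio": float(hap_expr[major_hap] / hap_expr[minor_hap]),
                }
            )
    true_ratios = pd.DataFrame(rows, columns=["subject_id", "marker_id", "true_ratio"])
    truth = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "diagnosis": diagnosis,
            "causal_dosage": causal.sum(axis=1).astype(int),
            "expressed": expressed,
            "fold_change": fold,
        }
    )
    return true_ratios, truth


def _sigma_log(linear_sd: float) -> float:
    """Log-normal sigma whose linear-scale SD at ratio 1 is ``linear_sd``.

    For X = exp(sigma Z), SD(X) = sqrt((e^{s^2}-1) e^{s^2}); solving the
    quadratic in e^{s^2} gives sigma exactly.
    """
    if linear_sd == 0:
        return 0.0
    y = (1.0 + math.sqrt(1.0 + 4.0 * linear_sd**2)) / 2.0
    return math.sqrt(math.log(y))


def simulate_measurements(
    true_ratios: pd.DataFrame,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Replicate allelic measurements around the true ratios.

    Each marker-heterozygous subject yields ``n_replicates_cdna`` cDNA rows
    with ratio = true ratio x multiplicative log-normal noise, and
    ``n_replicates_gdna`` gDNA rows centred at 1 with the gDNA noise SD.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for m in true_ratios["marker_id"].unique():
        if m not in noise.cdna_sd_by_marker or m not in noise.gdna_sd_by_marker:
            raise ConfigError(f"no noise SD configured for marker {m!r}")
    rows = []
    for rec in true_ratios.itertuples(index=False):
        s_c = _sigma_log(noise.cdna_sd_by_marker[rec.marker_id])
        s_g = _sigma_log(noise.gdna_sd_by_marker[rec.marker_id])
        for r in range(noise.n_replicates_cdna):
            val = rec.true_ratio * math.exp(rng.normal(0.0, s_c)) if s_c else rec.true_ratio
            rows.append((rec.subject_id, rec.marker_id, "cDNA", r + 1, val))
        for r in range(noise.n_replicates_gdna):
            val = math.exp(rng.normal(0.0, s_g)) if s_g else 1.0
            rows.append((rec.subject_id, rec.marker_id, "gDNA", r + 1, val))
    return pd.DataFrame(
        rows, columns=["subject_id", "marker_id", "source", "replicate", "ratio"]
    )


def generate_phenotypes(
    dosages: Sequence[float],
    phenotype: PhenotypeModel,
    subject_ids: Sequence[str],
    seed: int | np.random.Generator = 0,
    diagnosis: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary trait, count trait, sex and age for each subject.

    Sex and age are independent covariates used only for stratified
    re-analysis; they do not enter the trait models.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(dosages, dtype=float)
    n = d.size
    code = {
        "dominant": (d > 0).astype(float),
        "recessive": (d == 2).astype(float),
        "additive": d,
        "allelic": d,
    }[phenotype.model]
    base = phenotype.baseline_prevalence
    logit = math.log(base / (1 - base)) + math.log(phenotype.odds_ratio_per_unit) * code
    p_trait = 1.0 / (1.0 + np.exp(-logit))
    trait = (rng.random(n) < p_trait).astype(int)
    rate = phenotype.count_trait_rate_base * np.exp(
        phenotype.count_trait_log_rate_per_allele * d
    )
    episodes = rng.poisson(rate)
    sex = np.where(rng.random(n) < phenotype.female_fraction, "F", "M")
    lo, hi = phenotype.age_range
    age = rng.integers(lo, hi + 1, size=n)
    out = pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "diagnosis": list(diagnosis) if diagnosis is not None else ["na"] * n,
            "sex": sex,
            "age": age,
            "trait": trait,
            "episode_count": episodes,
        }
    )
    return out


@dataclass
class CohortTables:
    genotypes: GenotypeMatrix
    measurements: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    config: CohortSimConfig


def simulate_cohort(config: CohortSimConfig) -> CohortTables:
    """Run the full generator: haplotypes -> expression -> assay -> phenotypes.

    The stages consume one seeded random stream in a fixed order, so an
    identical configuration (including seed) reproduces every table
    byte-for-byte when written.
    """
    rng = np.random.default_rng(config.seed)
    diagnosis = [dx for dx, n in config.groups for _ in range(n)]
    n = len(diagnosis)
    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]

    haps = generate_haplotypes(config.snp_panel, config.ld, n, rng)
    true_ratios, truth = assign_allelic_expression(
        haps, config.snp_panel, config.effect, diagnosis, subject_ids, rng
    )
    measurements = simulate_measurements(true_ratios, config.noise, rng)

    snp_ids = [s.snp_id for s in config.snp_panel]
    dosage = pd.DataFrame(
        haps.sum(axis=1, dtype=float), index=subject_ids, columns=snp_ids
    )
    dosage.index.name = "subject_id"
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "maf_spec": [s.maf for s in config.snp_panel],
            "role": [s.role for s in config.snp_panel],
        }
    ).set_index("snp_id")
    genotypes = GenotypeMatrix(dosage, meta)

    pheno_snp = config.phenotype.snp_id or config.effect.causal_snp_id
    phenotypes = generate_phenotypes(
        dosage[pheno_snp].to_numpy(), config.phenotype, subject_ids, rng, diagnosis
    )
    truth = truth.merge(
        true_ratios.pivot(index="subject_id", columns="marker_id", values="true_ratio")
        .add_prefix("true_ratio_")
        .reset_index(),
        on="subject_id",
        how="left",
    )
    return CohortTables(genotypes, measurements, phenotypes, truth, config)


#: Table-1-style candidate panel: observed MAFs of the thirteen scanned variants
CANDIDATE_MAFS = {
    "rs851984": 0.385,
    "rs1285057": 0.374,
    "rs543650": 0.374,
    "rs488133": 0.312,
    "rs2071454": 0.122,
    "rs71685044": 0.456,
    "rs2077647": 0.500,
    "rs2234693": 0.490,
    "rs9340799": 0.361,
    "rs988328": 0.147,
    "rs3020327": 0.109,
    "rs3020329": 0.276,
}


def stanley_config(seed: int = 0) -> CohortSimConfig:
    """Default configuration emulating the brain-bank study conditions.

    Three diagnosis groups of 35 subjects; two transcribed marker SNPs with
    assay SDs 0.12/0.13 (cDNA) and 0.06/0.05 (gDNA); an intronic causal
    variant at MAF 0.181 in low LD with the markers (r2 0.003 and 0.044);
    twelve further candidate SNPs at their observed MAFs, in linkage
    equilibrium with the causal variant; the cis effect (fold change
    log-mean ln 3, log-sd 0.5) is expressed with penetrance 0.8 in disease
    and 0 in controls.
    """
    panel = [
        SnpSpec("rs3798577", 0.32, "marker"),
        SnpSpec("rs1801132", 0.20, "marker"),
        SnpSpec("rs2144025", 0.181, "causal"),
    ] + [SnpSpec(sid, maf, "candidate") for sid, maf in CANDIDATE_MAFS.items()]
    ld = [
        LdSpec("rs2144025", "rs3798577", 0.003),
        LdSpec("rs2144025", "rs1801132", 0.044),
    ]
    effect = EffectModel(
        causal_snp_id="rs2144025",
        fold_change_log_mean_by_state={
            "control": math.log(3.0),
            "bipolar": math.log(3.0),
            "schizophrenia": math.log(3.0),
        },
        fold_change_log_sd_by_state={
            "control": 0.5,
            "bipolar": 0.5,
            "schizophrenia": 0.5,
        },
        penetrance_by_state={"control": 0.0, "bipolar": 0.8, "schizophrenia": 0.8},
    )
    noise = NoiseModel(
        cdna_sd_by_marker={"rs3798577": 0.12, "rs1801132": 0.13},
        gdna_sd_by_marker={"rs3798577": 0.06, "rs1801132": 0.05},
    )
    return CohortSimConfig(
        groups=[("control", 35), ("bipolar", 35), ("schizophrenia", 35)],
        snp_panel=panel,
        ld=ld,
        effect=effect,
        noise=noise,
        phenotype=PhenotypeModel(),
        seed=seed,
    )
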