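"""YAML configuration for the cohort simulator and pipeline runs.

The file mirrors :class:`aeiscan.sim_cohort.CohortSimConfig` field names
exactly; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .sim_cohort import (
    CohortSimConfig,
    ConfigError,
    EffectModel,
    LdSpec,
    NoiseModel,
    PhenotypeModel,
    SnpSpec,
)

__all__ = ["load_config", "dump_config"]


def _strict_fields(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def load_config(path) -> CohortSimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    _strict_fields(
        raw,
        {"groups", "snp_panel", "ld", "effect", "noise", "phenotype", "seed"},
        str(path),
    )
    groups = [(g["diagnosis"], int(g["n"])) for g in raw["groups"]]
    panel = []
    for s in raw["snp_panel"]:
        _strict_fields(s, {"snp_id", "maf", "role"}, "snp_panel entry")
        panel.append(SnpSpec(s["snp_id"], float(s["maf"]), s.get("role", "candidate")))
    ld = []
    for pair in raw.get("ld", []) or []:
        _strict_fields(pair, {"snp_pair", "r2"}, "ld entry")
        a, b = pair["snp_pair"]
        ld.append(LdSpec(a, b, float(pair["r2"])))
    e = raw["effect"]
    _strict_fields(
        e,
        {
            "causal_snp_id",
            "fold_change_log_mean_by_state",
            "fold_change_log_sd_by_state",
            "penetrance_by_state",
        },
        "effect",
    )
    effect = EffectModel(
        causal_snp_id=e["causal_snp_id"],
        fold_change_log_mean_by_state={k: float(v) for k, v in e["fold_change_log_mean_by_state"].items()},
        fold_change_log_sd_by_state={k: float(v) for k, v in e["fold_change_log_sd_by_state"].items()},
        penetrance_by_state={k: float(v) for k, v in e["penetrance_by_state"].items()},
    )
    nz = raw["noise"]
    _strict_fields(
        nz,
        {"cdna_sd_by_marker", "gdna_sd_by_marker", "n_replicates_cdna", "n_replicates_gdna"},
        "noise",
    )
    noise = NoiseModel(
        cdna_sd_by_marker={k: float(v) for k, v in nz["cdna_sd_by_marker"].items()},
        gdna_sd_by_marker={k: float(v) for k, v in nz["gdna_sd_by_marker"].items()},
        n_replicates_cdna=int(nz.get("n_replicates_cdna", 3)),
        n_replicates_gdna=int(nz.get("n_replicates_gdna", 2)),
    )
    ph = raw.get("phenotype", {}) or {}
    _strict_fields(
        ph,
        {
            "baseline_prevalence",
            "model",
            "odds_ratio_per_unit",
            "count_trait_rate_base",
            "count_trait_log_rate_per_allele",
            "snp_id",
            "female_fraction",
            "age_range",
        },
        "phenotype",
    )
    kwargs = dict(ph)
    if "age_range" in kwargs:
        kwargs["age_range"] = tuple(kwargs["age_range"])
    phenotype = PhenotypeModel(**kwargs)
    return CohortSimConfig(
        groups=groups,
        snp_panel=panel,
        ld=ld,
        effect=effect,
        noise=noise,
        phenotype=phenotype,
        seed=int(raw.get("seed", 0)),
    )


def dump_config(config: CohortSimConfig, path) -> None:
    data = {
        "groups": [{"diagnosis": dx, "n": n} for dx, n in config.groups],
        "snp_panel": [
            {"snp_id": s.snp_id, "maf": s.maf, "role": s.role} for s in config.snp_panel
        ],
        "ld": [{"snp_pair": [p.snp_a, p.snp_b], "r2": p.r2} for p in config.ld],
        "effect": {
            "causal_snp_id": config.effect.causal_snp_id,
            "fold_change_log_mean_by_state": config.effect.fold_change_log_mean_by_state,
            "fold_change_log_sd_by_state": config.effect.fold_change_log_sd_by_state,
            "penetrance_by_state": config.effect.penetrance_by_state,
        },
        "noise": {
            "cdna_sd_by_marker": config.noise.cdna_sd_by_marker,
            "gdna_sd_by_marker": config.noise.gdna_sd_by_marker,
            "n_replicates_cdna": config.noise.n_replicates_cdna,
            "n_replicates_gdna": config.noise.n_replicates_gdna,
        },
        "phenotype": {
            "baseline_prevalence": config.phenotype.baseline_prevalence,
            "model": config.phenotype.model,
            "odds_ratio_per_unit": config.phenotype.odds_ratio_per_unit,
            "count_trait_rate_base": config.phenotype.count_trait_rate_base,
            "count_trait_log_rate_per_allele": config.phenotype.count_trait_log_rate_per_allele,
            "snp_id": config.phenotype.snp_id,
            "female_fraction": config.phenotype.female_fraction,
            "age_range": list(config.phenotype.age_range),
        },
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
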