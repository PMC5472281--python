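"""Readers and writers for the pipeline's table formats.

All tables are tab-separated UTF-8 with a mandatory header row and '.' for
missing values.  Genotypes can additionally be read from a minimal VCF
(biallelic SNPs, GT field), in which case dosages are recoded to
minor-allele counts: records whose ALT frequency exceeds 0.5 are flipped
(0 <-> 2) and flagged in the SNP metadata.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .aei_scan import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_aei",
    "write_aei",
]

MEASUREMENT_COLUMNS = ["subject_id", "marker_id", "source", "replicate", "ratio"]
MISSING = "."


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_measurements(path) -> pd.DataFrame:
    """Read a replicate allelic-measurement table, validating every record.

    The header must be exactly (subject_id, marker_id, source, replicate,
    ratio); sources must be cDNA or gDNA, ratios positive, and the
    (subject, marker, source, replicate) key unique.  Errors name the
    offending line (1-based, counting the header as line 1).
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if list(df.columns) != MEASUREMENT_COLUMNS:
        raise ValueError(
            f"{path}: header must be exactly {MEASUREMENT_COLUMNS}, got {list(df.columns)}"
        )
    lines = df.index + 2  # header is line 1
    bad = ~df["source"].isin(["cDNA", "gDNA"])
    if bad.any():
        raise ValueError(f"{path}: unknown source at line {lines[bad][0]}")
    try:
        ratio = df["ratio"].astype(float)
        replicate = df["replicate"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable numeric field ({exc})") from exc
    nonpos = ~(ratio > 0)
    if nonpos.any():
        raise ValueError(f"{path}: non-positive ratio at line {lines[nonpos][0]}")
    dup = df.duplicated(subset=["subject_id", "marker_id", "source", "replicate"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (subject, marker, source, replicate) at line {lines[dup][0]}"
        )
    out = df.copy()
    out["ratio"] = ratio
    out["replicate"] = replicate
    return out


def write_measurements(df: pd.DataFrame, path) -> None:
    _write_tsv(df[MEASUREMENT_COLUMNS], path)


def _genotypes_from_tsv(path) -> GenotypeMatrix:
    df = _read_tsv(path)
    required = {"subject_id", "snp_id", "dosage"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: genotype TSV needs columns {sorted(required)}")
    dosage = df["dosage"].astype(float)
    ok = dosage.isna() | dosage.isin([0.0, 1.0, 2.0])
    if not ok.all():
        line = (df.index + 2)[~ok][0]
        raise ValueError(f"{path}: dosage outside {{0,1,2,.}} at line {line}")
    wide = (
        df.assign(dosage=dosage)
        .pivot(index="subject_id", columns="snp_id", values="dosage")
        .rename_axis(index="subject_id", columns=None)
    )
    # preserve first-appearance SNP order rather than pivot's lexicographic one
    order = list(dict.fromkeys(df["snp_id"]))
    wide = wide[order]
    return GenotypeMatrix(wide, pd.DataFrame(index=pd.Index(order, name="snp_id")))


def _genotypes_from_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, rows, flips = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"{path}: skipping non-biallelic record {variant.ID or variant.POS}",
                stacklevel=2,
            )
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(variant.gt_types)
        alt_dosage = np.select(
            [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
        )
        present = ~np.isnan(alt_dosage)
        alt_freq = alt_dosage[present].sum() / (2 * present.sum()) if present.any() else 0.0
        flipped = alt_freq > 0.5
        dosage = 2.0 - alt_dosage if flipped else alt_dosage
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        rows.append(dosage)
        flips.append(flipped)
    dosage = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(subjects), 0)),
        index=pd.Index(subjects, name="subject_id"),
        columns=snp_ids,
    )
    meta = pd.DataFrame(
        {"minor_is_ref": flips}, index=pd.Index(snp_ids, name="snp_id")
    )
    return GenotypeMatrix(dosage, meta)


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read genotypes from TSV (long: subject_id, snp_id, dosage) or VCF.

    Format is inferred from the file extension unless given explicitly.
    Dosages are minor-allele counts; for VCF the minor allele is determined
    from the observed ALT frequency (ties kept as ALT).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "tsv":
        return _genotypes_from_tsv(path)
    if fmt == "vcf":
        return _genotypes_from_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Write genotypes as the long TSV (subject_id, snp_id, dosage)."""
    long = genotypes.dosage.reset_index().melt(
        id_vars="subject_id", var_name="snp_id", value_name="dosage"
    )
    # keep panel SNP order, not alphabetical
    order = {sid: k for k, sid in enumerate(genotypes.snp_ids)}
    long = long.sort_values(
        ["snp_id", "subject_id"], key=lambda s: s.map(order) if s.name == "snp_id" else s,
        kind="mergesort",
    )
    long["dosage"] = long["dosage"].map(lambda v: "." if pd.isna(v) else str(int(v)))
    _write_tsv(long, path)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table needs a subject_id column")
    for col in ("age", "trait", "episode_count"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path)


def read_aei(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("norm_ratio", "folded_ratio", "cdna_sd", "max_folded_ratio"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in ("category", "n_cdna", "n_gdna", "n_markers"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(int)
    if "cnv_flag" in df.columns:
        df["cnv_flag"] = df["cnv_flag"].map({"True": True, "False": False})
    return df


def write_aei(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path)
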