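"""Candidate-SNP scan for association with allelic expression imbalance.

AEI in a subject heterozygous for a cis-acting variant shows up regardless
of which haplotype carries the functional allele, so the natural screen is
heterozygosity itself: each candidate SNP is recoded het vs hom (either
homozygote), and the AEI outcome is compared between the two classes with a
one-way ANOVA F-test, Bonferroni-corrected for the number of SNPs tested.
The causal variant — or anything in strong LD with it — should separate the
classes; unrelated SNPs should not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .exact_stats import ContingencyTable

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "recode_het_hom", "scan", "category_by_group_table"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosages with per-SNP metadata.

    ``dosage`` is a float DataFrame indexed by subject_id with SNP columns;
    entries are 0/1/2 or NaN for missing.  ``metadata`` is indexed by
    snp_id (may carry e.g. an allele-flip flag from VCF import).
    """

    dosage: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def maf_observed(self) -> pd.Series:
        """Minor-allele frequency per SNP from non-missing dosages."""
        return self.dosage.sum(skipna=True) / (2 * self.dosage.notna().sum())


def recode_het_hom(dosage: float) -> int:
    """1 for heterozygous (dosage 1), 0 for either homozygote."""
    if dosage not in (0, 1, 2):
        raise ValueError("dosage must be 0, 1 or 2 (missing values are excluded upstream)")
    return 1 if dosage == 1 else 0


def scan(
    genotypes: GenotypeMatrix,
    aei: pd.DataFrame,
    response: str = "category",
) -> pd.DataFrame:
    """Screen every SNP for association with per-subject AEI.

    Parameters
    ----------
    genotypes
        Dosage matrix over the scannable subjects.
    aei
        Subject-level AEI table (from :func:`aeiscan.aei_quant.quantify`)
        with at least subject_id and the response column.
    response
        ``"category"`` (default) uses the ordinal AEI category 0/1/2 as a
        numeric response; ``"ratio"`` uses the continuous folded ratio
        (column ``max_folded_ratio``).

    Returns
    -------
    DataFrame with one row per SNP: snp_id, maf, n_used, n_het, f_stat,
    p_raw, p_bonf, testable — sorted by p_raw ascending, untestable SNPs
    last.  Missing genotypes are dropped pairwise per SNP; a SNP needs at
    least two subjects in each of the het and hom classes to be testable.
    Bonferroni multiplies by the number of SNPs attempted (testable or
    not) and clips at 1.
    """
    col = {"category": "category", "ratio": "max_folded_ratio"}.get(response)
    if col is None:
        raise ValueError("response must be 'category' or 'ratio'")
    if col not in aei.columns:
        raise ValueError(f"AEI table lacks column {col!r}")
    y = aei.set_index("subject_id")[col].astype(float)

    common = genotypes.dosage.index.intersection(y.index)
    if len(common) == 0:
        raise ValueError("no subjects shared between genotypes and AEI table")
    dropped = len(y) - len(common)
    if dropped:
        logger.info("%d AEI subjects lack genotypes and are excluded", dropped)
    dos = genotypes.dosage.loc[common]
    y = y.loc[common]

    m = len(dos.columns)
    rows = []
    for snp in dos.columns:
        d = dos[snp]
        mask = d.notna()
        n_missing = int((~mask).sum())
        if n_missing:
            logger.info("SNP %s: %d missing genotypes excluded", snp, n_missing)
        dv = d[mask]
        yv = y[mask].to_numpy()
        het = dv.to_numpy() == 1.0
        n_used = int(mask.sum())
        maf = float(dv.sum() / (2 * n_used)) if n_used else float("nan")
        n_het, n_hom = int(het.sum()), int((~het).sum())
        if n_het < 2 or n_hom < 2:
            rows.append((snp, maf, n_used, n_het, np.nan, np.nan, np.nan, False))
            continue
        if np.ptp(yv) == 0:
            f_stat, p_raw = 0.0, 1.0  # constant response carries no signal
        else:
            f_stat, p_raw = f_oneway(yv[het], yv[~het])
            if not np.isfinite(p_raw):
                f_stat, p_raw = 0.0, 1.0
        rows.append((snp, maf, n_used, n_het, float(f_stat), float(p_raw), np.nan, True))

    out = pd.DataFrame(
        rows,
        columns=["snp_id", "maf", "n_used", "n_het", "f_stat", "p_raw", "p_bonf", "testable"],
    )
    out["p_bonf"] = np.minimum(1.0, out["p_raw"] * m)
    out = out.sort_values(
        ["testable", "p_raw"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def category_by_group_table(
    categories: pd.Series, groups: pd.Series, group_order=None
) -> ContingencyTable:
    """Cross-tabulate AEI category (rows) against a grouping label (columns)."""
    cats = pd.Series(categories)
    grp = pd.Series(groups)
    if len(cats) != len(grp):
        raise ValueError("categories and groups must align")
    ct = pd.crosstab(cats, grp)
    if group_order is not None:
        ct = ct.reindex(columns=list(group_order), fill_value=0)
    return ContingencyTable(
        ct.to_numpy(),
        row_labels=[str(r) for r in ct.index],
        col_labels=[str(c) for c in ct.columns],
    )
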