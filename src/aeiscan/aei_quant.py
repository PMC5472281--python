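"""Quantification and classification of allelic expression imbalance (AEI).

A heterozygous marker SNP inside a transcript lets the two alleles' mRNA be
distinguished: the replicate cDNA allele-peak ratios, normalized to the same
subject's genomic-DNA ratio (which must be 1:1 absent copy-number changes),
estimate the cis-driven expression ratio of the two alleles.  Because the
marker is generally not the causal variant and not in LD with it, the
direction of imbalance is arbitrary; ratios are therefore *folded* to
high-expressing over low-expressing allele (>= 1) before classification.

Classification uses two cut-offs: a presence threshold derived from assay
replicate noise (1 + 3 SD of replicate cDNA ratios around unity) separating
no AEI from moderate AEI, and a fixed high threshold of 2.0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AeiThresholds",
    "NormalizedAEI",
    "DEFAULT_T_MODERATE",
    "DEFAULT_T_HIGH",
    "normalize_subject",
    "derive_threshold",
    "classify_aei",
    "reconcile_dual_markers",
    "gdna_cnv_check",
    "quantify",
]

DEFAULT_T_MODERATE = 1.4
DEFAULT_T_HIGH = 2.0

#: category meaning: 0 no AEI, 1 moderate AEI, 2 high AEI
NOT_EVALUABLE = -1


@dataclass(frozen=True)
class AeiThresholds:
    marker_id: str
    t_moderate: float = DEFAULT_T_MODERATE
    t_high: float = DEFAULT_T_HIGH

    def __post_init__(self) -> None:
        if not 1.0 < self.t_moderate < self.t_high:
            raise ValueError("need 1 < t_moderate < t_high")


@dataclass
class NormalizedAEI:
    subject_id: str
    marker_id: str
    norm_ratio: float
    folded_ratio: float
    cdna_sd: float
    n_cdna: int
    n_gdna: int
    category: int | None = None


def _check_ratios(name: str, ratios: Sequence[float]) -> np.ndarray:
    arr = np.asarray(ratios, dtype=float)
    if arr.size == 0:
        raise ValueError(f"no {name} replicates supplied")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} ratios must be finite and > 0")
    return arr


def normalize_subject(
    cdna_replicates: Sequence[float],
    gdna_replicates: Sequence[float],
    subject_id: str = "",
    marker_id: str = "",
    aggregation: str = "arithmetic",
) -> NormalizedAEI:
    """Normalize replicate cDNA allele ratios to the gDNA ratio.

    The normalized ratio is mean(cDNA) / mean(gDNA) (arithmetic means by
    default, geometric on request) and the folded ratio is
    max(norm, 1/norm).  ``cdna_sd`` is the sample SD of the cDNA replicates
    (ddof=1; zero for a single replicate).
    """
    cdna = _check_ratios("cDNA", cdna_replicates)
    gdna = _check_ratios("gDNA", gdna_replicates)
    if aggregation == "arithmetic":
        mean_c, mean_g = cdna.mean(), gdna.mean()
    elif aggregation == "geometric":
        mean_c = float(np.exp(np.log(cdna).mean()))
        mean_g = float(np.exp(np.log(gdna).mean()))
    else:
        raise ValueError("aggregation must be 'arithmetic' or 'geometric'")
    norm = float(mean_c / mean_g)
    sd = float(cdna.std(ddof=1)) if cdna.size > 1 else 0.0
    return NormalizedAEI(
        subject_id=subject_id,
        marker_id=marker_id,
        norm_ratio=norm,
        folded_ratio=max(norm, 1.0 / norm),
        cdna_sd=sd,
        n_cdna=int(cdna.size),
        n_gdna=int(gdna.size),
    )


def derive_threshold(replicate_sd: float, center: float = 1.0) -> float:
    """AEI-presence threshold: ``center + 3 * replicate_sd``.

    With the center fixed at unity (gDNA normalization guarantees null
    ratios sit at 1) and the assay's replicate SD, a folded ratio beyond
    3 SD is called a genuine imbalance.
    """
    if replicate_sd < 0:
        raise ValueError("replicate SD must be >= 0")
    return center + 3.0 * replicate_sd


def classify_aei(folded_ratio: float, thresholds: AeiThresholds) -> int:
    """Three-level AEI category from a folded ratio.

    0 below the moderate threshold, 1 from the moderate threshold up to and
    including the high threshold, 2 strictly above it.
    """
    if folded_ratio < 1.0:
        raise ValueError("folded ratio must be >= 1 (apply folding first)")
    if folded_ratio < thresholds.t_moderate:
        return 0
    if folded_ratio <= thresholds.t_high:
        return 1
    return 2


def reconcile_dual_markers(categories: Iterable[int]) -> int:
    """Subject-level category from one or two per-marker categories.

    Agreeing markers (or a single marker) keep their category; discordant
    markers are called moderate (category 1).
    """
    cats = list(categories)
    if not cats:
        raise ValueError("no marker categories to reconcile")
    if len(cats) > 2:
        raise ValueError("at most two marker categories expected")
    if len(cats) == 1 or cats[0] == cats[1]:
        return cats[0]
    return 1


def gdna_cnv_check(
    gdna_replicates: Sequence[float], tolerance: float = 3 * 0.05
) -> bool:
    """Flag possible copy-number variation from the genomic-DNA ratio.

    gDNA allele ratios must sit at unity for a diploid locus; a mean folded
    gDNA ratio exceeding ``1 + tolerance`` (strictly — the boundary itself
    passes) flags the subject for exclusion from AEI scanning.  The default
    tolerance is 3x the typical gDNA replicate SD.
    """
    arr = _check_ratios("gDNA", gdna_replicates)
    mean = float(arr.mean())
    folded = max(mean, 1.0 / mean)
    return folded > 1.0 + tolerance


def quantify(
    measurements: pd.DataFrame,
    thresholds: dict[str, AeiThresholds] | tuple[float, float] | str | None = None,
    aggregation: str = "arithmetic",
    cnv_tolerance_sd: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject AEI ratios and categories from a replicate measurement table.

    Parameters
    ----------
    measurements
        Long table with columns subject_id, marker_id, source (cDNA/gDNA),
        replicate, ratio — one row per replicate.  Only subjects
        heterozygous for a marker are measurable and hence present;
        subjects homozygous at every marker are simply absent (AEI is
        unobservable for them, not zero).
    thresholds
        ``None`` — fixed defaults (1.4, 2.0) for every marker;
        ``(t_mod, t_high)`` — explicit pair for every marker;
        ``"auto"`` — per-marker presence threshold 1 + 3 * median replicate
        cDNA SD, high threshold 2.0;
        or a dict marker_id -> AeiThresholds.

    Returns
    -------
    (aei, subjects)
        ``aei`` has one row per subject x marker with norm_ratio,
        folded_ratio, cdna_sd, category and a CNV flag; ``subjects`` holds
        the reconciled subject-level category (CNV-flagged subjects are
        excluded with a logged warning).
    """
    required = {"subject_id", "marker_id", "source", "replicate", "ratio"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements table lacks columns {sorted(missing)}")

    # assay-level gDNA replicate SD per marker (pooled across subjects): the
    # CNV tolerance must reflect the assay, not one subject's few replicates
    gdna_all = measurements[measurements["source"] == "gDNA"]
    pooled_sd: dict[str, float] = {}
    for marker, grp in gdna_all.groupby("marker_id"):
        per_subj_var = grp.groupby("subject_id")["ratio"].var(ddof=1).dropna()
        pooled_sd[str(marker)] = (
            float(np.sqrt(per_subj_var.mean())) if len(per_subj_var) else 0.0
        )

    rows: list[NormalizedAEI] = []
    cnv_flags: dict[tuple[str, str], bool] = {}
    for (subj, marker), grp in measurements.groupby(
        ["subject_id", "marker_id"], sort=True
    ):
        cdna = grp.loc[grp["source"] == "cDNA", "ratio"].to_numpy()
        gdna = grp.loc[grp["source"] == "gDNA", "ratio"].to_numpy()
        if cdna.size == 0 or gdna.size == 0:
            raise ValueError(f"subject {subj} marker {marker}: need both cDNA and gDNA")
        rec = normalize_subject(cdna, gdna, str(subj), str(marker), aggregation)
        sd = pooled_sd.get(str(marker), 0.0)
        cnv_flags[(str(subj), str(marker))] = gdna_cnv_check(
            gdna, tolerance=cnv_tolerance_sd * sd if sd > 0 else 3 * 0.05
        )
        rows.append(rec)

    aei = pd.DataFrame([vars(r) for r in rows]).drop(columns="category")

    # resolve thresholds per marker
    markers = sorted(aei["marker_id"].unique())
    table: dict[str, AeiThresholds] = {}
    if thresholds is None:
        table = {m: AeiThresholds(m) for m in markers}
    elif thresholds == "auto":
        for m in markers:
            sd = float(aei.loc[aei["marker_id"] == m, "cdna_sd"].median())
            t_mod = derive_threshold(sd)
            if t_mod <= 1.0:
                warnings.warn(
                    f"marker {m}: degenerate derived threshold; using default "
                    f"{DEFAULT_T_MODERATE}",
                    stacklevel=2,
                )
                t_mod = DEFAULT_T_MODERATE
            table[m] = AeiThresholds(m, t_mod, DEFAULT_T_HIGH)
    elif isinstance(thresholds, dict):
        table = dict(thresholds)
    else:
        t_mod, t_high = thresholds
        table = {m: AeiThresholds(m, t_mod, t_high) for m in markers}

    aei["category"] = [
        classify_aei(f, table[m]) for f, m in zip(aei["folded_ratio"], aei["marker_id"])
    ]
    aei["cnv_flag"] = [
        cnv_flags[(s, m)] for s, m in zip(aei["subject_id"], aei["marker_id"])
    ]

    subj_rows = []
    for subj, grp in aei.groupby("subject_id", sort=True):
        if grp["cnv_flag"].any():
            logger.warning(
                "subject %s flagged for gDNA ratio deviation (possible CNV); "
                "excluded from AEI scanning",
                subj,
            )
            continue
        subj_rows.append(
            {
                "subject_id": subj,
                "category": reconcile_dual_markers(grp["category"]),
                "max_folded_ratio": float(grp["folded_ratio"].max()),
                "n_markers": int(len(grp)),
            }
        )
    subjects = pd.DataFrame(
        subj_rows, columns=["subject_id", "category", "max_folded_ratio", "n_markers"]
    )
    return aei, subjects
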