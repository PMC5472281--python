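"""Genetic-model association statistics for case/control SNP data.

Covers the single-SNP toolbox of candidate-gene follow-up studies:

* reconstruction of 2x2 allele-count tables from published minor-allele
  frequencies and arm sizes,
* allelic / dominant / recessive collapses with Pearson chi-squared and
  Fisher exact p-values and Woolf (log-scale) odds-ratio confidence
  intervals,
* the Cochran–Armitage trend test for the additive model,
* an exact conditional Hardy–Weinberg equilibrium test,
* dosage vs count-trait Pearson correlation and per-stratum MAF summaries.

Covariates such as sex and age are handled by running the tests inside
strata rather than by covariate-adjusted regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import pearsonr

from .exact_stats import ContingencyTable, chi_squared, fisher_exact

__all__ = [
    "AlleleCountTable",
    "AssociationResult",
    "StratumSummary",
    "reconstruct_allele_counts",
    "odds_ratio_woolf",
    "model_test",
    "trend_test",
    "hwe_test",
    "dosage_trait_correlation",
    "maf_by_stratum",
]

MODELS = ("allelic", "dominant", "recessive", "additive")


@dataclass
class AlleleCountTable:
    """Minor/major allele counts for case and control arms."""

    minor_case: int
    major_case: int
    minor_control: int
    major_control: int

    def as_2x2(self) -> np.ndarray:
        return np.array(
            [
                [self.minor_case, self.major_case],
                [self.minor_control, self.major_control],
            ]
        )

    @property
    def maf_case(self) -> float:
        return self.minor_case / (self.minor_case + self.major_case)

    @property
    def maf_control(self) -> float:
        return self.minor_control / (self.minor_control + self.major_control)


@dataclass
class AssociationResult:
    model: str
    chi2_p: float
    fisher_p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int
    testable: bool = True


@dataclass
class StratumSummary:
    stratum: str
    maf: float
    n: int


def reconstruct_allele_counts(
    maf_case: float,
    n_case: int,
    maf_control: float,
    n_control: int,
    printed_precision: float = 0.001,
) -> AlleleCountTable:
    """Rebuild a 2x2 allele-count table from printed MAFs and subject counts.

    Each arm contributes 2n alleles; the minor count is the nearest integer
    to ``2 n maf`` (ties to even).  A warning is emitted when the rebuilt
    MAF differs from the input by more than half the printed precision —
    the published figure then cannot correspond to an integer allele count.
    """
    for maf, n in ((maf_case, n_case), (maf_control, n_control)):
        if not 0.0 <= maf <= 1.0:
            raise ValueError("MAF must lie in [0, 1]")
        if n < 1:
            raise ValueError("arm size must be >= 1")
    minor_case = int(np.round(2 * n_case * maf_case))
    minor_control = int(np.round(2 * n_control * maf_control))
    table = AlleleCountTable(
        minor_case, 2 * n_case - minor_case, minor_control, 2 * n_control - minor_control
    )
    for label, rebuilt, target in (
        ("case", table.maf_case, maf_case),
        ("control", table.maf_control, maf_control),
    ):
        if abs(rebuilt - target) > 0.5 * printed_precision:
            warnings.warn(
                f"{label} arm: reconstructed MAF {rebuilt:.5f} deviates from the "
                f"printed {target} by more than half its precision",
                stacklevel=2,
            )
    return table


def odds_ratio_woolf(table, ci_multiplier: float = 1.96):
    """Odds ratio with the Woolf log-scale confidence interval.

    For counts ``[[a, b], [c, d]]`` (case exposed/unexposed over control
    exposed/unexposed) the OR is ``ad/bc`` and the CI is
    ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  A zero cell
    triggers the Haldane–Anscombe +0.5 correction on all cells, with a
    warning.
    """
    if isinstance(table, AlleleCountTable):
        cells = table.as_2x2().astype(float)
    else:
        cells = np.asarray(table, dtype=float)
    if cells.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    if np.any(cells == 0):
        warnings.warn(
            "zero cell in 2x2 table; applying Haldane-Anscombe 0.5 correction",
            stacklevel=2,
        )
        cells = cells + 0.5
    a, b = cells[0]
    c, d = cells[1]
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - ci_multiplier * se)),
        float(np.exp(log_or + ci_multiplier * se)),
    )


def _collapse(case: Sequence[int], control: Sequence[int], model: str) -> np.ndarray:
    """Collapse genotype counts (n0, n1, n2) per arm to a model 2x2.

    Rows are case/control; column 0 is the "exposed" class (minor alleles,
    carriers, or minor homozygotes depending on the model).
    """
    c0, c1, c2 = case
    k0, k1, k2 = control
    if model == "allelic":
        return np.array([[c1 + 2 * c2, 2 * c0 + c1], [k1 + 2 * k2, 2 * k0 + k1]])
    if model == "dominant":
        return np.array([[c1 + c2, c0], [k1 + k2, k0]])
    if model == "recessive":
        return np.array([[c2, c0 + c1], [k2, k0 + k1]])
    raise ValueError(f"unknown model {model!r}")


def trend_test(case: Sequence[int], control: Sequence[int], scores=(0.0, 1.0, 2.0)):
    """Cochran–Armitage trend test on a 2 x k genotype table.

    Score-weighted comparison of case fractions across genotype columns;
    the statistic is chi-squared with 1 df under the null of no trend.
    Returns ``(statistic, p)``.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    s = np.asarray(scores, dtype=float)
    col = case + control
    n = col.sum()
    n_case = case.sum()
    if n_case == 0 or n_case == n:
        warnings.warn("one arm is empty; trend test degenerate", stacklevel=2)
        return 0.0, 1.0
    pbar = n_case / n
    u = float((s * (case - pbar * col)).sum())
    var = pbar * (1 - pbar) * float((s**2 * col).sum() - (s * col).sum() ** 2 / n)
    if var <= 0:
        return 0.0, 1.0
    stat = u**2 / var
    return float(stat), float(_chi2_dist.sf(stat, 1))


def model_test(case: Sequence[int], control: Sequence[int], model: str) -> AssociationResult:
    """Run one genetic-model association test on genotype counts per arm.

    ``case`` and ``control`` are (n0, n1, n2) counts of minor-allele
    dosage.  Allelic/dominant/recessive collapse to a 2x2 and report
    Pearson chi-squared (no continuity correction), the exact Fisher p,
    and the Woolf OR with 95% CI.  The additive model reports the
    Cochran–Armitage trend p (as chi2_p), the Freeman–Halton exact p of
    the 2x3 genotype table, and the allelic-collapse OR as the per-allele
    effect summary.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    case = tuple(int(x) for x in case)
    control = tuple(int(x) for x in control)
    n = sum(case) + sum(control)
    if sum(case) < 2 or sum(control) < 2:
        raise ValueError("need at least 2 subjects per arm")

    if model == "additive":
        stat, p_trend = trend_test(case, control)
        table23 = np.array([case, control])
        if np.any(table23.sum(axis=0) == 0):
            fisher_p = float("nan")
        else:
            fisher_p = fisher_exact(table23).p_two_sided
        or_, lo, hi = odds_ratio_woolf(_collapse(case, control, "allelic"))
        return AssociationResult("additive", p_trend, fisher_p, or_, lo, hi, n)

    t22 = _collapse(case, control, model)
    if np.any(t22.sum(axis=0) == 0):
        warnings.warn(f"{model} collapse has an empty class; untestable", stacklevel=2)
        nan = float("nan")
        return AssociationResult(model, nan, nan, nan, nan, nan, n, testable=False)
    _, _, chi2_p = chi_squared(t22)
    fisher_p = fisher_exact(t22).p_two_sided
    or_, lo, hi = odds_ratio_woolf(t22)
    return AssociationResult(model, chi2_p, fisher_p, or_, lo, hi, n)


def hwe_test(genotype_counts: Sequence[int]) -> float:
    """Exact conditional test of Hardy–Weinberg equilibrium.

    Conditions on the observed minor-allele count and enumerates every
    heterozygote count of the same parity; the two-sided p is the total
    probability of configurations no more probable than the observed one
    (probability-mass convention).  Monomorphic samples return p = 1.
    """
    n0, n1, n2 = (int(x) for x in genotype_counts)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 < 1:
        raise ValueError("genotype counts must be non-negative with n >= 1")
    n = n0 + n1 + n2
    n_minor = n1 + 2 * n2
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0

    def log_prob(nhet: int) -> float:
        nhom2 = (n_minor - nhet) // 2
        nhom0 = n - nhet - nhom2
        # P(nhet | n, n_minor) up to the margin constant (shared, cancels)
        return float(
            nhet * np.log(2)
            + gammaln(n + 1)
            - gammaln(nhom0 + 1)
            - gammaln(nhet + 1)
            - gammaln(nhom2 + 1)
            - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(2 * n - n_minor + 1))
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    log_ps = {h: log_prob(h) for h in hets}
    log_obs = log_ps[n1]
    p = sum(np.exp(lp) for lp in log_ps.values() if lp <= log_obs + np.log1p(1e-7))
    return float(min(p, 1.0))


def dosage_trait_correlation(dosages, counts):
    """Pearson correlation between minor-allele dosage and a count trait.

    Returns ``(r, p)`` with the p-value from the t transform on n-2 df.
    Constant dosage or trait makes the correlation undefined: (nan, nan)
    with a warning.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(counts, dtype=float)
    if d.size != y.size or d.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(d) == 0 or np.ptp(y) == 0:
        warnings.warn("constant dosage or trait; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = pearsonr(d, y)
    return float(r), float(p)


def maf_by_stratum(dosages, strata, order: Sequence[str] | None = None) -> list[StratumSummary]:
    """Per-stratum minor-allele frequency and subject count.

    Missing dosages (NaN) are ignored within each stratum; empty strata are
    dropped with a warning.  ``order`` fixes the report order (e.g. ordered
    age-of-onset bins); otherwise strata appear in sorted label order.
    """
    d = np.asarray(dosages, dtype=float)
    s = np.asarray(strata)
    if d.size != s.size:
        raise ValueError("dosages and strata must align")
    labels = list(order) if order is not None else sorted(set(map(str, s)))
    out = []
    for lab in labels:
        mask = (s.astype(str) == lab) & ~np.isnan(d)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"stratum {lab!r} is empty; dropped", stacklevel=2)
            continue
        out.append(StratumSummary(lab, float(d[mask].sum() / (2 * n)), n))
    return out
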