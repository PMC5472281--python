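"""Exact and asymptotic tests for r x c contingency tables.

The centrepiece is the Freeman–Halton generalisation of Fisher's exact test:
conditional on both margins, every table is assigned its multivariate
hypergeometric probability and the two-sided p-value is the total probability
of tables no more probable than the one observed (the probability-mass
convention).  Probabilities are accumulated in log space from log-factorials,
so tables with large margins do not overflow.

For tables whose margin set admits too many candidate tables to enumerate, a
seeded Monte-Carlo estimate conditioned on the same margins is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "fisher_exact",
    "fisher_exact_mc",
    "chi_squared",
    "TooManyTablesError",
]

#: relative tolerance used when comparing table probabilities to the observed
#: one, so that exact ties are not lost to floating point rounding
TIE_REL_TOL = 1e-7

#: enumeration guard: above this many candidate tables fisher_exact refuses
#: and suggests the Monte-Carlo estimator
MAX_TABLES = 20_000_000


class TooManyTablesError(RuntimeError):
    """Raised when exhaustive enumeration would exceed ``MAX_TABLES``."""


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts with axis labels."""

    counts: np.ndarray
    row_labels: Sequence[str] = field(default_factory=list)
    col_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 1 or c.shape[1] < 1:
            raise ValueError("contingency table must be a 2-D count array")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        if c.sum() <= 0:
            raise ValueError("table total must be positive")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(c.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(c.shape[1])]

    @classmethod
    def from_string(cls, text: str) -> "ContingencyTable":
        """Parse ``"17,6,1;10,9,7"`` into a table (rows separated by ';')."""
        rows = [[int(x) for x in row.split(",")] for row in text.split(";")]
        if len({len(r) for r in rows}) != 1:
            raise ValueError("ragged table specification")
        return cls(np.array(rows))

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExactTestResult:
    p_two_sided: float
    n_tables_enumerated: int
    observed_prob: float
    method: str = "freeman-halton"


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def _degenerate(table: ContingencyTable) -> bool:
    r, c = table.counts.shape
    if r < 2 or c < 2:
        warnings.warn("table has fewer than 2 rows or columns; p is degenerate (1.0)",
                      stacklevel=3)
        return True
    if np.any(table.row_margins == 0) or np.any(table.col_margins == 0):
        warnings.warn(
            "table has a zero row or column margin; exact p is degenerate (1.0)",
            stacklevel=3,
        )
        return True
    return False


def _log_margin_const(table: ContingencyTable) -> float:
    """log of prod(r_i!) prod(c_j!) / n! — constant across tables with fixed margins."""
    return float(
        gammaln(table.row_margins + 1).sum()
        + gammaln(table.col_margins + 1).sum()
        - gammaln(table.total + 1)
    )


def _iter_tables(row_margins, col_margins, cap):
    """Yield every non-negative integer table with the given margins.

    Depth-first over cells, rows top to bottom; the last cell of each row and
    the whole last row are forced, which keeps the search tree tight.  Raises
    TooManyTablesError once more than ``cap`` tables have been produced.
    """
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)
    col_left = np.array(col_margins, dtype=np.int64)
    produced = 0

    def rec(i: int):
        nonlocal produced
        if i == r - 1:
            if np.all(col_left >= 0) and col_left.sum() == row_margins[i]:
                table[i, :] = col_left
                produced += 1
                if produced > cap:
                    raise TooManyTablesError(
                        f"more than {cap} tables share these margins; "
                        "use fisher_exact_mc"
                    )
                yield table
            return
        yield from rec_cell(i, 0, row_margins[i])

    def rec_cell(i: int, j: int, row_left: int):
        if j == c - 1:
            if 0 <= row_left <= col_left[j]:
                table[i, j] = row_left
                col_left[j] -= row_left
                yield from rec(i + 1)
                col_left[j] += row_left
            return
        hi = min(row_left, col_left[j])
        for v in range(hi + 1):
            table[i, j] = v
            col_left[j] -= v
            yield from rec_cell(i, j + 1, row_left - v)
            col_left[j] += v

    yield from rec(0)


def fisher_exact(table, max_tables: int = MAX_TABLES) -> ExactTestResult:
    """Two-sided Freeman–Halton exact test on an r x c table.

    The p-value is the sum of multivariate hypergeometric probabilities of
    every table sharing the observed margins whose probability does not
    exceed the observed table's (within ``TIE_REL_TOL`` relative tolerance).
    For 2x2 tables this reduces to the classical two-sided Fisher test.
    """
    t = _as_table(table)
    if _degenerate(t):
        return ExactTestResult(1.0, 0, 1.0)
    log_const = _log_margin_const(t)
    log_p_obs = log_const - float(gammaln(t.counts + 1).sum())
    p_obs = float(np.exp(log_p_obs))
    threshold = log_p_obs + np.log1p(TIE_REL_TOL)

    p_sum = 0.0
    n_tables = 0
    for cand in _iter_tables(t.row_margins, t.col_margins, max_tables):
        log_p = log_const - float(gammaln(cand + 1).sum())
        n_tables += 1
        if log_p <= threshold:
            p_sum += float(np.exp(log_p))
    return ExactTestResult(min(p_sum, 1.0), n_tables, p_obs)


def fisher_exact_mc(table, n_samples: int = 10_000, seed: int = 0) -> ExactTestResult:
    """Monte-Carlo estimate of the Freeman–Halton p-value.

    Samples tables from the null conditional distribution by randomly
    re-pairing row and column labels (equivalent to uniform sampling of
    tables weighted by their hypergeometric probability) and applies the
    add-one estimator (k+1)/(B+1), which is never exactly zero.
    """
    t = _as_table(table)
    if _degenerate(t):
        return ExactTestResult(1.0, 0, 1.0, method="monte-carlo")
    rng = np.random.default_rng(seed)
    log_const = _log_margin_const(t)
    log_p_obs = log_const - float(gammaln(t.counts + 1).sum())
    threshold = log_p_obs + np.log1p(TIE_REL_TOL)

    n = t.total
    r, c = t.counts.shape
    row_of = np.repeat(np.arange(r), t.row_margins)
    col_of = np.repeat(np.arange(c), t.col_margins)
    k = 0
    for _ in range(n_samples):
        perm_cols = col_of[rng.permutation(n)]
        cand = np.zeros((r, c), dtype=np.int64)
        np.add.at(cand, (row_of, perm_cols), 1)
        log_p = log_const - float(gammaln(cand + 1).sum())
        if log_p <= threshold:
            k += 1
    p = (k + 1) / (n_samples + 1)
    return ExactTestResult(
        min(p, 1.0), n_samples, float(np.exp(log_p_obs)), method="monte-carlo"
    )


def chi_squared(table, continuity_correction: bool = False):
    """Pearson chi-squared test of independence.

    Returns ``(statistic, df, p)``.  The Yates continuity correction is off
    by default and only applies to 2x2 tables.  A zero margin makes the test
    degenerate (statistic 0, p 1, with a warning).
    """
    t = _as_table(table)
    if _degenerate(t):
        return 0.0, 0, 1.0
    expected = np.outer(t.row_margins, t.col_margins) / t.total
    resid = np.abs(t.counts - expected)
    if continuity_correction and t.counts.shape == (2, 2):
        resid = np.maximum(resid - 0.5, 0.0)
    stat = float((resid**2 / expected).sum())
    df = (t.counts.shape[0] - 1) * (t.counts.shape[1] - 1)
    p = float(_chi2_dist.sf(stat, df))
    return stat, df, p
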