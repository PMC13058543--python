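"""Exact contingency-table inference under the margin-fixed model.

With all margins of a 2x2 table fixed, the top-left cell count X follows
Fisher's noncentral hypergeometric distribution indexed by the odds ratio
psi:

    P(X = x | psi)  propto  C(m, x) C(n, k - x) psi^x

over the support max(0, k-n) <= x <= min(k, m), where m and n are the row
totals and k is the first-column total.  This one family yields everything
this module computes:

* the two-sided Fisher exact p-value (sum of central, psi = 1, probabilities
  no larger than the observed one, with a relative slack of 1e-7 to absorb
  floating-point ties — the convention of R's ``fisher.test``);
* the conditional maximum-likelihood odds ratio, i.e. the psi at which the
  expected cell count equals the observed one (distinct from, and weakly
  closer to 1 than, the crude cross-product ratio ad/bc);
* exact tail-inversion confidence intervals for the odds ratio;
* the exact test for r x c tables via enumeration of all tables sharing the
  observed margins under the multivariate hypergeometric null.

All probability work is done in log space, so totals in the thousands are
handled without under/overflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

#: relative slack when comparing table probabilities against the observed one
P_TIE_SLACK = 1e-7

#: relative tolerance for odds-ratio root finding
_ROOT_RTOL = 1e-9

#: search window for log(psi) in root finding; psi in [e^-50, e^50] comfortably
#: covers any table whose cells fit in memory
_LOG_PSI_LIMIT = 50.0


class DegenerateTableError(ValueError):
    """A margin needed for inference is zero."""


@dataclass(frozen=True)
class Table2x2:
    """2x2 counts; rows = exposure levels in listed order, cols = (non_critical, critical).

    The odds ratio psi is oriented as a*d / (b*c): psi > 1 means the second
    row carries higher odds of the second-column outcome.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "Table2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))

    @property
    def rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.a + self.b, self.c + self.d), (self.a + self.c, self.b + self.d)

    def is_degenerate(self) -> bool:
        (r1, r2), (c1, c2) = self.margins
        return min(r1, r2, c1, c2) == 0


@dataclass(frozen=True)
class TableRxC:
    """General r x c count table with fixed margins (r, c >= 2)."""

    counts: tuple[tuple[int, ...], ...]

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[int]]) -> "TableRxC":
        counts = tuple(tuple(int(v) for v in row) for row in rows)
        if len(counts) < 2 or any(len(row) != len(counts[0]) for row in counts):
            raise ValueError("table must be rectangular with >= 2 rows")
        if len(counts[0]) < 2:
            raise ValueError("table must have >= 2 columns")
        if any(v < 0 for row in counts for v in row):
            raise ValueError("cells must be non-negative")
        if sum(v for row in counts for v in row) < 1:
            raise ValueError("grand total must be >= 1")
        return cls(counts)

    @property
    def row_margins(self) -> tuple[int, ...]:
        return tuple(sum(row) for row in self.counts)

    @property
    def col_margins(self) -> tuple[int, ...]:
        return tuple(sum(col) for col in zip(*self.counts))


@dataclass(frozen=True)
class ExactTestResult:
    """Two-sided exact p, conditional-MLE odds ratio, and exact CI."""

    p_two_sided: float
    or_cmle: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    estimate_kind: str = "conditional_mle"


# ---------------------------------------------------------------------------
# noncentral hypergeometric pmf
# ---------------------------------------------------------------------------

def _support(m: int, n: int, k: int) -> np.ndarray:
    return np.arange(max(0, k - n), min(k, m) + 1)


def _log_weights(m: int, n: int, k: int, support: np.ndarray, psi: float) -> np.ndarray:
    """Unnormalized log pmf over the support (psi = 0 handled by the caller)."""
    x = support
    logw = (
        gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)
        + gammaln(n + 1) - gammaln(k - x + 1) - gammaln(n - (k - x) + 1)
    )
    if psi != 1.0:
        logw = logw + x * math.log(psi)
    return logw


def nchg_pmf(x: int, m: int, n: int, k: int, psi: float) -> float:
    """Fisher noncentral hypergeometric pmf P(X = x | m, n, k, psi).

    ``m`` marked and ``n`` unmarked items, ``k`` drawn; psi is the odds
    multiplier on marked items.  psi = 1 recovers the central hypergeometric.
    Values of ``x`` outside the support return 0.
    """
    if psi < 0:
        raise ValueError(f"psi must be >= 0, got {psi}")
    support = _support(m, n, k)
    if x < support[0] or x > support[-1]:
        return 0.0
    if psi == 0.0:
        return 1.0 if x == support[0] else 0.0
    logw = _log_weights(m, n, k, support, psi)
    return float(np.exp(logw[x - support[0]] - logsumexp(logw)))


def _conditional_dist(table: Table2x2, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and normalized probabilities of the a-cell at odds ratio e^log_psi."""
    (m, n), (k, _) = table.margins
    support = _support(m, n, k)
    x = support
    logw = (
        gammaln(m + 1) - gammaln(x + 1) - gammaln(m - x + 1)
        + gammaln(n + 1) - gammaln(k - x + 1) - gammaln(n - (k - x) + 1)
        + x * log_psi
    )
    logw -= logw.max()
    w = np.exp(logw)
    return support, w / w.sum()


# ---------------------------------------------------------------------------
# Fisher exact test, 2x2
# ---------------------------------------------------------------------------

def fisher_2x2(table: Table2x2) -> float:
    """Two-sided Fisher exact p-value by probability-mass ordering.

    Sums the central hypergeometric probabilities of all tables with the
    observed margins whose probability is at most the observed table's,
    within relative slack ``P_TIE_SLACK``.  A zero margin makes the table
    non-informative: p = 1 by convention.
    """
    if table.is_degenerate():
        logger.warning("fisher_2x2: zero margin in %s; p = 1 by convention", table.rows)
        return 1.0
    support, probs = _conditional_dist(table, 0.0)
    p_obs = probs[table.a - support[0]]
    p = float(probs[probs <= p_obs * (1.0 + P_TIE_SLACK)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# conditional MLE odds ratio and exact CI
# ---------------------------------------------------------------------------

def _check_margins(table: Table2x2) -> None:
    (r1, r2), (c1, c2) = table.margins
    for name, v in (("row 1", r1), ("row 2", r2), ("column 1", c1), ("column 2", c2)):
        if v == 0:
            raise DegenerateTableError(f"{name} margin is zero; odds ratio undefined")


def _solve_log_psi(fn, increasing: bool) -> float:
    """Root of a monotone function of log(psi) on the fixed search window."""
    lo, hi = -_LOG_PSI_LIMIT, _LOG_PSI_LIMIT
    flo, fhi = fn(lo), fn(hi)
    if not increasing:
        flo, fhi = -flo, -fhi
        g = lambda t: -fn(t)  # noqa: E731
    else:
        g = fn
    if flo >= 0:
        return lo
    if fhi <= 0:
        return hi
    return brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)


def cmle_odds_ratio(table: Table2x2) -> float:
    """Conditional maximum-likelihood odds ratio.

    The psi at which the expected a-cell count under the noncentral
    hypergeometric model equals the observed count.  Returns 0 when the
    observed cell sits at the bottom of its support and ``inf`` at the top.
    The expectation is strictly increasing in psi, so the root is unique;
    it is bracketed on log(psi) and refined with Brent's method.
    """
    _check_margins(table)
    (m, n), (k, _) = table.margins
    support = _support(m, n, k)
    if table.a == support[0]:
        return 0.0
    if table.a == support[-1]:
        return math.inf

    def mean_minus_obs(log_psi: float) -> float:
        s, probs = _conditional_dist(table, log_psi)
        return float((s * probs).sum()) - table.a

    return math.exp(_solve_log_psi(mean_minus_obs, increasing=True))


def crude_odds_ratio(table: Table2x2) -> float:
    """Cross-product (unconditional sample) odds ratio a*d / (b*c)."""
    if table.b * table.c == 0:
        if table.a * table.d == 0:
            raise DegenerateTableError("0/0 crude odds ratio")
        return math.inf
    return (table.a * table.d) / (table.b * table.c)


def exact_or_ci(table: Table2x2, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact tail-inversion confidence interval for the odds ratio.

    The lower bound is the psi at which P(X >= x_obs) equals alpha/2; the
    upper bound the psi at which P(X <= x_obs) equals alpha/2.  At the
    support boundaries the corresponding limit is 0 or ``inf``.
    """
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    _check_margins(table)
    (m, n), (k, _) = table.margins
    support = _support(m, n, k)
    alpha = (1.0 - conf_level) / 2.0

    if support[0] == support[-1]:
        return 0.0, math.inf  # single-point support: no information about psi

    idx = table.a - support[0]

    def upper_tail_minus_alpha(log_psi: float) -> float:
        _, probs = _conditional_dist(table, log_psi)
        return float(probs[idx:].sum()) - alpha

    def lower_tail_minus_alpha(log_psi: float) -> float:
        _, probs = _conditional_dist(table, log_psi)
        return float(probs[: idx + 1].sum()) - alpha

    if table.a == support[0]:
        ci_low = 0.0
    else:
        # P(X >= x_obs) increases with psi
        ci_low = math.exp(_solve_log_psi(upper_tail_minus_alpha, increasing=True))
    if table.a == support[-1]:
        ci_high = math.inf
    else:
        ci_high = math.exp(_solve_log_psi(lower_tail_minus_alpha, increasing=False))
    return ci_low, ci_high


def exact_test_2x2(table: Table2x2, conf_level: float = 0.95) -> ExactTestResult:
    """Bundle p-value, conditional-MLE odds ratio and exact CI for a 2x2 table."""
    p = fisher_2x2(table)
    if table.is_degenerate():
        return ExactTestResult(
            p_two_sided=p, or_cmle=math.nan, ci_low=math.nan, ci_high=math.nan,
            conf_level=conf_level,
        )
    return ExactTestResult(
        p_two_sided=p,
        or_cmle=cmle_odds_ratio(table),
        ci_low=exact_or_ci(table, conf_level)[0],
        ci_high=exact_or_ci(table, conf_level)[1],
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# r x c exact test
# ---------------------------------------------------------------------------

class EnumerationCapExceeded(RuntimeError):
    """The r x c enumeration would visit more tables than the configured cap."""


def fisher_rxc(table: TableRxC | Sequence[Sequence[int]], max_tables: int = 10_000_000) -> float:
    """Two-sided exact test for an r x c table with fixed margins.

    Enumerates every non-negative integer table with the observed row and
    column margins (recursive margin-constrained fill) and sums the
    multivariate hypergeometric probabilities of those no more probable than
    the observed table, with the same tie slack as :func:`fisher_2x2`.
    Raises :class:`EnumerationCapExceeded` rather than silently
    approximating if the workload would exceed ``max_tables``.
    """
    if not isinstance(table, TableRxC):
        table = TableRxC.from_rows(table)
    if min(table.row_margins) == 0 or min(table.col_margins) == 0:
        # an all-zero row/column carries no information; test the rest
        kept_rows = [r for r in table.counts if sum(r) > 0]
        kept_cols = [j for j in range(len(table.counts[0]))
                     if sum(row[j] for row in table.counts) > 0]
        trimmed = [[row[j] for j in kept_cols] for row in kept_rows]
        if len(trimmed) < 2 or len(trimmed[0]) < 2:
            logger.warning("fisher_rxc: table degenerate after trimming; p = 1 by convention")
            return 1.0
        table = TableRxC.from_rows(trimmed)
    rows = table.row_margins
    cols = table.col_margins
    n = sum(rows)
    lgam = gammaln(np.arange(n + 2))  # lgam[v] = log((v-1)!); use lgam[v+1] = log v!

    # constant part of log P(T): sum log r_i! + sum log c_j! - log n!
    log_const = float(sum(lgam[r + 1] for r in rows) + sum(lgam[c + 1] for c in cols) - lgam[n + 1])

    def log_prob(cells: Sequence[int]) -> float:
        return log_const - float(sum(lgam[v + 1] for v in cells))

    obs_cells = [v for row in table.counts for v in row]
    log_p_obs = log_prob(obs_cells)
    threshold = log_p_obs + math.log1p(P_TIE_SLACK)

    r, c = len(rows), len(cols)
    visited = 0
    acc = 0.0  # accumulated probability of tables at or below the observed mass

    # depth-first fill, row by row; within a row, cell by cell with the last
    # cell forced by the row margin
    def fill_row(i: int, col_rem: list[int], log_fact_sum: float) -> None:
        nonlocal visited, acc
        if i == r - 1:
            # last row forced by column remainders
            if any(v < 0 for v in col_rem):
                return
            visited += 1
            if visited > max_tables:
                raise EnumerationCapExceeded(
                    f"more than {max_tables} tables share these margins; "
                    "raise max_tables or use a Monte Carlo method"
                )
            lp = log_const - log_fact_sum - float(sum(lgam[v + 1] for v in col_rem))
            if lp <= threshold:
                acc += math.exp(lp)
            return

        row_total = rows[i]

        def fill_cell(j: int, rem: int, partial: float, new_col_rem: list[int]) -> None:
            if j == c - 1:
                if rem > new_col_rem[j]:
                    return
                new_col_rem2 = new_col_rem.copy()
                new_col_rem2[j] -= rem
                fill_row(i + 1, new_col_rem2, partial + float(lgam[rem + 1]))
                return
            for v in range(min(rem, new_col_rem[j]) + 1):
                nxt = new_col_rem.copy()
                nxt[j] -= v
                fill_cell(j + 1, rem - v, partial + float(lgam[v + 1]), nxt)

        fill_cell(0, row_total, log_fact_sum, col_rem)

    fill_row(0, list(cols), 0.0)
    return min(acc, 1.0)
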