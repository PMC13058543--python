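"""Arbitrary-precision reference implementations used only to validate the
log-space inference engine.  Everything here is exact rational arithmetic on
integer cell counts; nothing is shared with the implementation under test."""

from __future__ import annotations

from fractions import Fraction
from math import comb

#: integer version of the implementation's 1 + 1e-7 tie slack
_SLACK_NUM, _SLACK_DEN = 10**7 + 1, 10**7


def nchg_pmf_exact(x: int, m: int, n: int, k: int, psi: Fraction) -> Fraction:
    """Noncentral hypergeometric pmf with exact rationals."""
    lo, hi = max(0, k - n), min(k, m)
    if not lo <= x <= hi:
        return Fraction(0)
    total = sum(comb(m, u) * comb(n, k - u) * psi**u for u in range(lo, hi + 1))
    return comb(m, x) * comb(n, k - x) * psi**x / total


def fisher_2x2_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by complete support enumeration in integers.

    The tie comparison w_x <= w_obs * (1 + 1e-7) is carried out exactly on
    the integer hypergeometric weights.
    """
    m, n, k = a + b, c + d, a + c
    if min(m, n, k, b + d) == 0:
        return Fraction(1)
    lo, hi = max(0, k - n), min(k, m)
    weights = {x: comb(m, x) * comb(n, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w * _SLACK_DEN <= w_obs * _SLACK_NUM)
    return Fraction(num, sum(weights.values()))


def _tables_with_margins(rows: tuple[int, ...], cols: tuple[int, ...]):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(rows), len(cols)

    def fill(i: int, col_rem: tuple[int, ...], acc: tuple[tuple[int, ...], ...]):
        if i == r - 1:
            if all(v >= 0 for v in col_rem) and sum(col_rem) == rows[i]:
                yield acc + (col_rem,)
            return
        def cells(j: int, rem: int, row: tuple[int, ...]):
            if j == c - 1:
                if rem <= col_rem[j]:
                    yield row + (rem,)
                return
            for v in range(min(rem, col_rem[j]) + 1):
                yield from cells(j + 1, rem - v, row + (v,))
        for row in cells(0, rows[i], ()):
            new_rem = tuple(cr - v for cr, v in zip(col_rem, row))
            yield from fill(i + 1, new_rem, acc + (row,))

    yield from fill(0, cols, ())


def _table_weight(table, n_total: int) -> int:
    """Integer weight proportional to the multivariate hypergeometric probability.

    P(T) = (prod r_i! prod c_j!) / (N! prod n_ij!); the margin factorials are
    common to all tables, so weight = N! / prod n_ij! (a multinomial count).
    """
    from math import factorial

    w = factorial(n_total)
    for row in table:
        for v in row:
            w //= factorial(v)
    return w


def fisher_rxc_exact(observed) -> Fraction:
    """Exact r x c two-sided p by brute-force margin-constrained enumeration."""
    rows = tuple(sum(r) for r in observed)
    cols = tuple(sum(col) for col in zip(*observed))
    n_total = sum(rows)
    obs = tuple(tuple(int(v) for v in row) for row in observed)
    w_obs = _table_weight(obs, n_total)
    num = 0
    den = 0
    for table in _tables_with_margins(rows, cols):
        w = _table_weight(table, n_total)
        den += w
        if w * _SLACK_DEN <= w_obs * _SLACK_NUM:
            num += w
    return Fraction(num, den)
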