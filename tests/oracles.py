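"""Independent exact-rational oracles used by the test suite.

Everything here is computed with big-integer factorials and
``fractions.Fraction`` — no log-gamma, no floating point, and no calls into
the package's own kernels — so these values can arbitrate the package's
log-space arithmetic.  Valid only for integer counts with unit concentration
(a = 1), which is where the factorial identities hold.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np


def dirichlet_fn(values) -> Fraction:
    """Exact D(v) = prod Gamma(v_i) / Gamma(sum v_i) for positive integers."""
    values = [int(v) for v in np.asarray(values).ravel()]
    assert all(v > 0 for v in values)
    num = 1
    for v in values:
        num *= factorial(v - 1)
    return Fraction(num, factorial(sum(values) - 1))


def _margins(t):
    t = np.asarray(t, dtype=int)
    return t.sum(axis=1), t.sum(axis=0), int(t.sum())


def bf10_poisson(t) -> Fraction:
    t = np.asarray(t, dtype=int)
    R, C = t.shape
    r, c, n = _margins(t)
    b = Fraction(R * C, n)
    xi_total = R * C - (R - 1) * (C - 1)
    bf01 = (1 + 1 / b) ** ((R - 1) * (C - 1))
    bf01 *= Fraction(factorial(n + xi_total - 1), factorial(xi_total - 1))
    for y in t.ravel():
        bf01 *= Fraction(1, factorial(int(y)))
    bf01 *= dirichlet_fn(r + 1) / dirichlet_fn([1] * R)
    bf01 *= dirichlet_fn(c + 1) / dirichlet_fn([1] * C)
    return 1 / bf01


def bf10_joint_multinomial(t) -> Fraction:
    t = np.asarray(t, dtype=int)
    R, C = t.shape
    r, c, _ = _margins(t)
    bf01 = dirichlet_fn(r + 1) / dirichlet_fn([1] * R)
    bf01 *= dirichlet_fn(c + 1) / dirichlet_fn([1] * C)
    bf01 *= dirichlet_fn([1] * (R * C)) / dirichlet_fn(t + 1)
    return 1 / bf01


def bf10_independent_multinomial_rows(t) -> Fraction:
    t = np.asarray(t, dtype=int)
    R, C = t.shape
    r, c, _ = _margins(t)
    bf01 = dirichlet_fn(c + 1) / dirichlet_fn([1] * C)
    bf01 *= dirichlet_fn(r + C) / dirichlet_fn([C] * R)
    bf01 *= dirichlet_fn([1] * (R * C)) / dirichlet_fn(t + 1)
    return 1 / bf01


def _compositions(total, parts):
    """All ways to write ``total`` as an ordered sum of ``parts`` naturals."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def brute_force_fixed_margin_tables(row_totals, col_totals):
    """All tables with the given margins: unconstrained row compositions,
    filtered on the column sums afterwards (no pruning; tiny inputs only)."""
    row_totals = [int(v) for v in row_totals]
    col_totals = [int(v) for v in col_totals]
    C = len(col_totals)
    out = []
    for rows in itertools.product(*(_compositions(rt, C) for rt in row_totals)):
        t = np.array(rows)
        if list(t.sum(axis=0)) == col_totals:
            out.append(t)
    return out


def bf10_hypergeometric(t, enumerator=None) -> Fraction:
    """Exact fixed-margin Bayes factor by summation over all completions."""
    t = np.asarray(t, dtype=int)
    r, c, n = _margins(t)

    def multinomial_coef(parts) -> Fraction:
        v = Fraction(factorial(n))
        for p in np.asarray(parts).ravel():
            v /= factorial(int(p))
        return v

    tables = (
        brute_force_fixed_margin_tables(r, c) if enumerator is None else list(enumerator(r, c))
    )
    numerator = sum(
        multinomial_coef(tab) * dirichlet_fn(np.asarray(tab) + 1) for tab in tables
    )
    denominator = multinomial_coef(r) * multinomial_coef(c) * dirichlet_fn(t + 1)
    return denominator / numerator  # BF10 = 1 / BF01


def bf10_eq17_min_margin(t) -> Fraction:
    """Jeffreys-style factorial closed form with the smallest margin first."""
    t = np.asarray(t, dtype=int)
    r, c, n = _margins(t)
    if min(c) < min(r):
        t = t.T
        r, c = c, r
    if r[1] < r[0]:
        t = t[::-1]
        r = r[::-1]
    num = factorial(int(t[0, 0])) * factorial(int(t[0, 1]))
    num *= factorial(int(t[1, 0])) * factorial(int(t[1, 1])) * factorial(n)
    den = factorial(int(r[0]) + 1) * factorial(int(r[1]))
    den *= factorial(int(c[0])) * factorial(int(c[1]))
    return Fraction(num, den)


def chi_square(t) -> Fraction:
    """Exact Pearson statistic sum((o - e)^2 / e) in rational arithmetic."""
    t = np.asarray(t, dtype=int)
    r, c, n = _margins(t)
    total = Fraction(0)
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = Fraction(int(r[i]) * int(c[j]), n)
            total += (int(t[i, j]) - e) ** 2 / e
    return total


def central_hypergeometric_pmf(y11, row_totals, col_totals) -> Fraction:
    y1, (c1, c2) = int(row_totals[0]), [int(v) for v in col_totals]
    lo, hi = max(0, y1 - c2), min(y1, c1)
    if not lo <= y11 <= hi:
        return Fraction(0)
    return Fraction(comb(c1, y11) * comb(c2, y1 - y11), comb(c1 + c2, y1))


def random_2x2(rng, cell_max=50):
    """A random valid 2x2 table with non-zero margins."""
    while True:
        t = rng.integers(0, cell_max + 1, size=(2, 2))
        if t.sum() > 0 and t.sum(axis=1).min() > 0 and t.sum(axis=0).min() > 0:
            return t
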