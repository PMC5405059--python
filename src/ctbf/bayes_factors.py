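"""Default Bayes factors for independence in R x C contingency tables.

Four sampling schemes are supported, in order of increasing restriction:

``poisson``
    Nothing is fixed; each cell count is Poisson with a gamma(a, b) prior on
    its rate.
``joint_multinomial``
    The grand total is fixed; the cell probabilities carry a Dirichlet(a)
    prior.
``independent_multinomial``
    One margin (rows or columns) is fixed by design; counts are multinomial
    within each fixed group.
``hypergeometric``
    Both margins are fixed; the data reduce to the cell pattern given the
    margins.

Each kernel computes the natural-log Bayes factor BF10 in favor of the
row-column *dependence* model H1 over the independence model H0.  The
marginal-likelihood ratios themselves are ratios of Dirichlet normalizing
constants and are evaluated entirely in log-gamma space; the hypergeometric
scheme additionally sums over every table sharing the observed margins
(log-sum-exp over an exhaustive enumeration).

For 2x2 tables with unit concentration (a = 1) each kernel collapses to a
closed form in factorials; those closed forms are implemented separately in
:func:`closed_form_2x2` and serve as independent cross-checks on the general
kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.special import gammaln, logsumexp

from .priors import PriorSpec, log_dirichlet, prior_for_table, xi_quantities
from .tables import ContingencyTable, TableShapeError, canonicalize_min_margin

__all__ = [
    "SCHEMES",
    "BayesFactorResult",
    "EnumerationCapError",
    "UnsupportedCombinationError",
    "logbf10_poisson",
    "logbf10_joint_multinomial",
    "logbf10_independent_multinomial",
    "logbf10_hypergeometric",
    "closed_form_2x2",
    "enumerate_fixed_margin_tables",
    "count_fixed_margin_tables",
    "noncentral_hypergeometric_pmf",
    "bayes_factor",
]

#: Canonical scheme names and accepted CLI-style aliases.
SCHEMES = {
    "poisson": "poisson",
    "joint_multinomial": "joint_multinomial",
    "jointmn": "joint_multinomial",
    "independent_multinomial": "independent_multinomial",
    "indepmn": "independent_multinomial",
    "hypergeometric": "hypergeometric",
    "hypergeom": "hypergeometric",
}

DEFAULT_ENUMERATION_CAP = 10**7


class EnumerationCapError(RuntimeError):
    """The fixed-margin enumeration would exceed the configured cap."""


class UnsupportedCombinationError(ValueError):
    """A scheme/shape/direction combination the method does not define."""


def _norm_scheme(scheme: str) -> str:
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(set(SCHEMES.values()))}")


def _check_prior(table: ContingencyTable, prior: PriorSpec) -> None:
    if prior.shape != table.shape:
        raise ValueError(
            f"prior shape {prior.shape} does not match table shape {table.shape}"
        )


@dataclass(frozen=True)
class BayesFactorResult:
    """Outcome of an independence test under one sampling scheme.

    ``log_bf10`` is the natural-log Bayes factor for dependence (H1) over
    independence (H0); ``bf01 = 1/bf10``.  ``fixed_margin`` records the
    design constraint: ``none`` (Poisson), ``total`` (joint multinomial),
    ``rows``/``columns`` (independent multinomial), or ``both``
    (hypergeometric).
    """

    scheme: str
    fixed_margin: str
    direction: str
    log_bf10: float
    prior: PriorSpec

    @property
    def bf10(self) -> float:
        return math.exp(self.log_bf10)

    @property
    def log_bf01(self) -> float:
        return -self.log_bf10

    @property
    def bf01(self) -> float:
        return math.exp(-self.log_bf10)

    @property
    def posterior_prob_h1(self) -> float:
        """P(H1 | data) under equal prior model probabilities."""
        from .evidence import posterior_probability_from_bf

        return posterior_probability_from_bf(log_bf10=self.log_bf10)

    @property
    def evidence_category(self):
        from .evidence import jeffreys_category

        return jeffreys_category(log_bf10=self.log_bf10)

    def to_dict(self) -> dict:
        cat = self.evidence_category
        return {
            "scheme": self.scheme,
            "fixed_margin": self.fixed_margin,
            "direction": self.direction,
            "log_bf10": self.log_bf10,
            "bf10": self.bf10,
            "bf01": self.bf01,
            "posterior_prob_h1": self.posterior_prob_h1,
            "evidence_category": cat.label,
            "prior_a": self.prior.scalar_a,
            "prior_b": self.prior.poisson_scale_b,
        }


# ---------------------------------------------------------------------------
# The four kernels
# ---------------------------------------------------------------------------

def logbf10_poisson(table: ContingencyTable, prior: PriorSpec) -> float:
    """Natural-log BF10 when nothing is fixed (Poisson cell counts).

    Requires ``prior.poisson_scale_b``; the conventional default is
    ``b = R*C*a / y..``.
    """
    _check_prior(table, prior)
    b = prior.poisson_scale_b
    if b is None:
        raise ValueError("the Poisson scheme needs prior.poisson_scale_b (default R*C*a/y..)")
    R, C = table.shape
    y = table.counts
    n = table.grand_total
    xi = xi_quantities(prior)
    log_bf01 = (
        (R - 1) * (C - 1) * math.log1p(1.0 / b)
        + float(gammaln(n + xi.xi_total) - gammaln(xi.xi_total))
        + float((gammaln(prior.concentration) - gammaln(y + prior.concentration)).sum())
        + log_dirichlet(table.row_totals + xi.xi_row)
        - log_dirichlet(xi.xi_row)
        + log_dirichlet(table.col_totals + xi.xi_col)
        - log_dirichlet(xi.xi_col)
    )
    return -log_bf01


def logbf10_joint_multinomial(table: ContingencyTable, prior: PriorSpec) -> float:
    """Natural-log BF10 when only the grand total is fixed."""
    _check_prior(table, prior)
    xi = xi_quantities(prior)
    log_bf01 = (
        log_dirichlet(table.row_totals + xi.xi_row)
        - log_dirichlet(xi.xi_row)
        + log_dirichlet(table.col_totals + xi.xi_col)
        - log_dirichlet(xi.xi_col)
        + log_dirichlet(prior.concentration)
        - log_dirichlet(table.counts + prior.concentration)
    )
    return -log_bf01


def logbf10_independent_multinomial(
    table: ContingencyTable, prior: PriorSpec, fixed_margin: str = "rows"
) -> float:
    """Natural-log BF10 when one margin is fixed by design.

    ``fixed_margin`` names the margin the sampling plan fixed ("rows" when
    the row totals are the group sizes).  The columns-fixed variant is the
    same expression with rows and columns interchanged.
    """
    if fixed_margin not in ("rows", "columns"):
        raise ValueError(f"fixed_margin must be 'rows' or 'columns', got {fixed_margin!r}")
    if fixed_margin == "columns":
        return logbf10_independent_multinomial(
            table.transposed(),
            PriorSpec(prior.concentration.T, prior.poisson_scale_b),
            "rows",
        )
    _check_prior(table, prior)
    xi = xi_quantities(prior)
    log_bf01 = (
        log_dirichlet(table.col_totals + xi.xi_col)
        - log_dirichlet(xi.xi_col)
        + log_dirichlet(table.row_totals + prior.row_sums())
        - log_dirichlet(prior.row_sums())
        + log_dirichlet(prior.concentration)
        - log_dirichlet(table.counts + prior.concentration)
    )
    return -log_bf01


def _log_multinomial_coef(n: int, parts) -> float:
    parts = np.asarray(parts, dtype=float).ravel()
    return float(gammaln(n + 1) - gammaln(parts + 1).sum())


def logbf10_hypergeometric(
    table: ContingencyTable,
    prior: PriorSpec,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> float:
    """Natural-log BF10 when both margins are fixed.

    The marginal likelihood under H1 sums, over every non-negative integer
    table sharing the observed margins, the multinomial coefficient times the
    Dirichlet mass of that table; the sum is accumulated by log-sum-exp over
    an exhaustive enumeration.  Tables whose margins admit more than
    ``enumeration_cap`` completions raise :class:`EnumerationCapError`
    (for a 2x2 table with a = 1 the factorial closed form
    ``closed_form_2x2(..., "hypergeometric")`` is equivalent and cheap).
    """
    _check_prior(table, prior)
    n = table.grand_total
    a = prior.concentration
    terms = []
    for i, t in enumerate(
        enumerate_fixed_margin_tables(table.row_totals, table.col_totals)
    ):
        if i >= enumeration_cap:
            raise EnumerationCapError(
                f"more than {enumeration_cap} tables share these margins; "
                "use the 2x2 closed form or raise enumeration_cap"
            )
        terms.append(_log_multinomial_coef(n, t) + log_dirichlet(t + a))
    log_numerator = float(logsumexp(terms))
    log_bf01 = (
        log_numerator
        - log_dirichlet(table.counts + a)
        - _log_multinomial_coef(n, table.row_totals)
        - _log_multinomial_coef(n, table.col_totals)
    )
    return -log_bf01


# ---------------------------------------------------------------------------
# 2x2 closed forms at a = 1 (independent cross-checks for the kernels)
# ---------------------------------------------------------------------------

def _lfact(x) -> float:
    return float(gammaln(np.asarray(x, dtype=float) + 1.0))


def _log_binom(n, k) -> float:
    return _lfact(n) - _lfact(k) - _lfact(n - k)


def _log_factorial_bracket(table: ContingencyTable) -> float:
    """log of y11! y12! y21! y22! y..! / ((y1.+1)! y2.! y.1! y.2!)."""
    y = table.counts
    r, c, n = table.row_totals, table.col_totals, table.grand_total
    return (
        sum(_lfact(v) for v in y.ravel())
        + _lfact(n)
        - _lfact(r[0] + 1)
        - _lfact(r[1])
        - _lfact(c[0])
        - _lfact(c[1])
    )


def closed_form_2x2(
    table: ContingencyTable, scheme: str, fixed_margin: str = "rows"
) -> float:
    """Natural-log BF10 from the factorial closed forms (2x2, a = 1 only).

    The hypergeometric form is stated for a table whose first row total is
    the smallest of the four margins and is therefore evaluated after
    min-margin canonicalization.  The independent-multinomial form treats the
    fixed margin totals as the two group sizes and the first free-category
    count in each group as the successes.
    """
    if table.shape != (2, 2):
        raise TableShapeError(f"closed forms require a 2x2 table, got {table.shape}")
    scheme = _norm_scheme(scheme)
    n = table.grand_total
    if scheme == "poisson":
        r = table.row_totals
        lead = math.log(8.0 * (n + 1) * (r[0] + 1)) - math.log((n + 4.0) * (n + 2.0))
        return lead + _log_factorial_bracket(table)
    if scheme == "joint_multinomial":
        r = table.row_totals
        lead = math.log(6.0 * (n + 1) * (r[0] + 1)) - math.log((n + 3.0) * (n + 2.0))
        return lead + _log_factorial_bracket(table)
    if scheme == "independent_multinomial":
        t = table if fixed_margin == "rows" else table.transposed()
        sizes = t.row_totals
        successes = t.counts[:, 0]
        log_bf01 = (
            _log_binom(sizes[0], successes[0])
            + _log_binom(sizes[1], successes[1])
            - _log_binom(n, successes.sum())
            + math.log((sizes[0] + 1.0) * (sizes[1] + 1.0))
            - math.log(n + 1.0)
        )
        return -log_bf01
    # hypergeometric
    canon, _ = canonicalize_min_margin(table)
    return _log_factorial_bracket(canon)


# ---------------------------------------------------------------------------
# Fixed-margin enumeration and the noncentral hypergeometric pmf
# ---------------------------------------------------------------------------

def enumerate_fixed_margin_tables(row_totals, col_totals) -> Iterator[np.ndarray]:
    """Yield every non-negative integer matrix with the given margins.

    Tables are generated row by row; within a row, cell values are bounded by
    the remaining column capacity, and a branch is pruned as soon as the
    remaining row total cannot be absorbed by the remaining columns.  Each
    table is yielded exactly once.
    """
    rt = [int(v) for v in np.asarray(row_totals).ravel()]
    ct = [int(v) for v in np.asarray(col_totals).ravel()]
    if any(v < 0 for v in rt + ct):
        raise ValueError("margins must be non-negative")
    if sum(rt) != sum(ct):
        raise ValueError(f"inconsistent margins: row sum {sum(rt)} != column sum {sum(ct)}")
    R, C = len(rt), len(ct)
    work = np.zeros((R, C), dtype=np.int64)

    def fill_row(r: int, remaining_cols: list[int]) -> Iterator[np.ndarray]:
        if r == R:
            # margins guarantee remaining_cols is all zero here
            yield work.copy()
            return
        target = rt[r]

        def fill_cell(c: int, left: int) -> Iterator[np.ndarray]:
            if c == C - 1:
                if left <= remaining_cols[c]:
                    work[r, c] = left
                    remaining_cols[c] -= left
                    yield from fill_row(r + 1, remaining_cols)
                    remaining_cols[c] += left
                return
            tail_capacity = sum(remaining_cols[c + 1:])
            lo = max(0, left - tail_capacity)
            hi = min(left, remaining_cols[c])
            for v in range(lo, hi + 1):
                work[r, c] = v
                remaining_cols[c] -= v
                yield from fill_cell(c + 1, left - v)
                remaining_cols[c] += v

        yield from fill_cell(0, target)

    yield from fill_row(0, list(ct))


def count_fixed_margin_tables(row_totals, col_totals, cap: int | None = None) -> int:
    """Number of tables with the given margins (optionally stopping at cap)."""
    count = 0
    for _ in enumerate_fixed_margin_tables(row_totals, col_totals):
        count += 1
        if cap is not None and count > cap:
            return count
    return count


def noncentral_hypergeometric_pmf(y11: int, row_totals, col_totals, psi: float) -> float:
    """P(Y11 = y11 | margins, odds ratio psi) for a 2x2 table.

    This is Fisher's noncentral hypergeometric distribution; at ``psi = 1``
    it reduces to the central hypergeometric.  Values of ``y11`` outside the
    support ``max(0, y1. - y.2) <= y11 <= min(y1., y.1)`` return probability
    0 rather than raising.
    """
    rt = np.asarray(row_totals, dtype=int).ravel()
    ct = np.asarray(col_totals, dtype=int).ravel()
    if rt.size != 2 or ct.size != 2:
        raise TableShapeError("the noncentral hypergeometric pmf is defined for 2x2 margins")
    if rt.sum() != ct.sum():
        raise ValueError("inconsistent margins")
    if not psi > 0:
        raise ValueError("psi must be > 0")
    y1, c1, c2 = int(rt[0]), int(ct[0]), int(ct[1])
    lo, hi = max(0, y1 - c2), min(y1, c1)
    if not lo <= y11 <= hi:
        return 0.0
    support = np.arange(lo, hi + 1)
    log_terms = (
        np.array([_log_binom(c1, i) + _log_binom(c2, y1 - i) for i in support])
        + support * math.log(psi)
    )
    target = _log_binom(c1, y11) + _log_binom(c2, y1 - y11) + y11 * math.log(psi)
    return float(math.exp(target - logsumexp(log_terms)))


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

_FIXED_FOR_SCHEME = {
    "poisson": "none",
    "joint_multinomial": "total",
    "hypergeometric": "both",
}


def bayes_factor(
    table: ContingencyTable,
    scheme: str,
    prior: PriorSpec | None = None,
    a: float = 1.0,
    b: float | None = None,
    fixed_margin: str | None = None,
    direction: str = "two_sided",
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> BayesFactorResult:
    """Compute the independence Bayes factor under a named sampling scheme.

    ``prior`` defaults to the uniform concentration ``a`` with the standard
    Poisson scale ``b = R*C*a / y..``.  One-sided directions ("greater" /
    "less", meaning the first-group success rate exceeds or trails the
    second's) are defined only for 2x2 tables under the independent
    multinomial scheme.
    """
    scheme = _norm_scheme(scheme)
    if prior is None:
        prior = prior_for_table(table, a=a, b=b)
    if scheme == "independent_multinomial":
        if fixed_margin is None:
            fixed_margin = "rows"
        if fixed_margin not in ("rows", "columns"):
            raise ValueError(f"fixed_margin must be 'rows' or 'columns', got {fixed_margin!r}")
    else:
        fixed_margin = _FIXED_FOR_SCHEME[scheme]

    if direction not in ("two_sided", "greater", "less"):
        raise ValueError(f"direction must be two_sided/greater/less, got {direction!r}")
    if direction != "two_sided" and (
        scheme != "independent_multinomial" or table.shape != (2, 2)
    ):
        raise UnsupportedCombinationError(
            "one-sided Bayes factors are defined only for 2x2 tables under "
            "the independent multinomial scheme"
        )

    if scheme == "poisson":
        log_bf10 = logbf10_poisson(table, prior)
    elif scheme == "joint_multinomial":
        log_bf10 = logbf10_joint_multinomial(table, prior)
    elif scheme == "independent_multinomial":
        log_bf10 = logbf10_independent_multinomial(table, prior, fixed_margin)
    else:
        log_bf10 = logbf10_hypergeometric(table, prior, enumeration_cap)

    if direction != "two_sided":
        from .directional import TwoProportionData, onesided_log_bf

        scalar_a = prior.scalar_a
        if scalar_a is None:
            raise UnsupportedCombinationError(
                "one-sided Bayes factors require a symmetric (scalar) prior"
            )
        data = TwoProportionData.from_table(table, fixed_margin=fixed_margin, prior_a=scalar_a)
        log_bf10 = onesided_log_bf(data, log_bf10, direction)

    return BayesFactorResult(
        scheme=scheme,
        fixed_margin=fixed_margin,
        direction=direction,
        log_bf10=float(log_bf10),
        prior=prior,
    )
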