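"""One-sided Bayes factors for the 2x2 comparison of two proportions.

Under the independent multinomial scheme the 2x2 independence test reduces
to comparing two binomial success rates theta_1 and theta_2 (one per fixed
group).  A directional alternative H+ : theta_1 > theta_2 (or H-) is scored
by the encompassing-prior mass ratio: the two-sided BF10 is multiplied by
the ratio of posterior to prior mass consistent with the order restriction.
For a symmetric prior the prior mass is exactly 1/2, so the correction is
``2 * P(theta_1 > theta_2 | data)`` and can never exceed 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from scipy import integrate, stats

from .tables import ContingencyTable, TableShapeError

__all__ = [
    "TwoProportionData",
    "posterior_prob_theta1_gt_theta2",
    "onesided_log_bf",
    "onesided_bf",
]


@dataclass(frozen=True)
class TwoProportionData:
    """Success counts and group sizes for two independent binomials.

    With a symmetric beta concentration ``prior_a`` per group, the posterior
    for group i's rate is Beta(successes_i + a, size_i - successes_i + a).
    """

    successes: tuple[int, int]
    group_sizes: tuple[int, int]
    prior_a: float = 1.0

    def __post_init__(self) -> None:
        s1, s2 = self.successes
        n1, n2 = self.group_sizes
        if n1 < 1 or n2 < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 <= s1 <= n1 and 0 <= s2 <= n2):
            raise ValueError("successes must satisfy 0 <= successes <= group size")
        if not self.prior_a > 0:
            raise ValueError("prior_a must be > 0")

    @classmethod
    def from_table(
        cls, table: ContingencyTable, fixed_margin: str = "rows", prior_a: float = 1.0
    ) -> "TwoProportionData":
        """Read the two groups off a 2x2 table.

        With rows fixed, the group sizes are the row totals and the successes
        are the first-column counts (so theta_1 is the first row's rate of
        the first outcome).
        """
        if table.shape != (2, 2):
            raise TableShapeError("two-proportion data requires a 2x2 table")
        t = table if fixed_margin == "rows" else table.transposed()
        return cls(
            successes=(int(t.counts[0, 0]), int(t.counts[1, 0])),
            group_sizes=(int(t.row_totals[0]), int(t.row_totals[1])),
            prior_a=prior_a,
        )

    def posterior_params(self) -> tuple[tuple[float, float], tuple[float, float]]:
        a = self.prior_a
        (s1, s2), (n1, n2) = self.successes, self.group_sizes
        return (s1 + a, n1 - s1 + a), (s2 + a, n2 - s2 + a)


def _beta_frac(m: int, n: int) -> Fraction:
    """Exact beta function B(m, n) for positive integers."""
    return Fraction(math.factorial(m - 1) * math.factorial(n - 1), math.factorial(m + n - 1))


def _prob_gt_exact(a1: int, b1: int, a2: int, b2: int) -> Fraction:
    """Exact P(X > Y), X ~ Beta(a1,b1), Y ~ Beta(a2,b2), integer parameters.

    Finite-sum identity for integer shape parameters; evaluated in rational
    arithmetic, so the result is exact.
    """
    den_b = _beta_frac(a2, b2)
    total = Fraction(0)
    for i in range(a1):
        total += _beta_frac(a2 + i, b1 + b2) / ((b1 + i) * _beta_frac(1 + i, b1) * den_b)
    return total


def posterior_prob_theta1_gt_theta2(data: TwoProportionData) -> float:
    """P(theta_1 > theta_2) under independent beta posteriors.

    Uses the exact finite-sum form when all posterior parameters are
    integers (the default a = 1 path), otherwise adaptive quadrature of
    ``f1(x) * F2(x)``.
    """
    (a1, b1), (a2, b2) = data.posterior_params()
    if all(float(v).is_integer() for v in (a1, b1, a2, b2)):
        return float(_prob_gt_exact(int(a1), int(b1), int(a2), int(b2)))
    integrand = lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a2, b2)
    value, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-10, limit=200)
    return float(min(max(value, 0.0), 1.0))


def onesided_log_bf(
    data: TwoProportionData, logbf10_twosided: float, direction: str
) -> float:
    """Natural-log BF+0 (or BF-0) from the two-sided log BF10.

    ``log BF(+/-)0 = log(2 p) + log BF10`` where p is the posterior mass in
    the stated direction; the factor-2 simplification holds because the
    symmetric prior puts mass exactly 1/2 on each ordering.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    p = posterior_prob_theta1_gt_theta2(data)
    if direction == "less":
        p = 1.0 - p
    if p == 0.0:
        return -math.inf
    return math.log(2.0 * p) + logbf10_twosided


def onesided_bf(data: TwoProportionData, bf10_twosided: float, direction: str) -> float:
    """Convenience wrapper returning BF(+/-)0 on the raw scale."""
    return math.exp(onesided_log_bf(data, math.log(bf10_twosided), direction))
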