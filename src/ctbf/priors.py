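"""Prior specification and shared notational machinery.

All four independence Bayes factors are built from the same ingredients: a
matrix of Dirichlet/gamma concentration parameters ``a_rc`` (one pseudo-count
per cell; ``a = 1`` is the uniform default), a gamma scale parameter ``b``
used only by the Poisson scheme (default ``b = R*C*a / y..``), the
margin-adjusted "xi" totals, and the Dirichlet normalizing function

    D(a) = prod_i Gamma(a_i) / Gamma(sum_i a_i),

which this module computes in natural-log space throughout, since realistic
tables require Gamma arguments in the hundreds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PriorSpec",
    "XiQuantities",
    "default_prior",
    "xi_quantities",
    "log_dirichlet",
]


@dataclass(frozen=True)
class PriorSpec:
    """Concentration matrix ``a_rc`` plus the Poisson gamma scale ``b``.

    ``poisson_scale_b`` is data-dependent under the default rule
    ``b = R*C*a / y..`` and is therefore only set once the grand total is
    known (see :func:`default_prior`); it may be overridden with any positive
    value.  Schemes other than Poisson ignore it.
    """

    concentration: np.ndarray
    poisson_scale_b: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.concentration, dtype=float)
        if arr.ndim != 2:
            raise ValueError("concentration must be a 2-D matrix")
        if not np.all(arr > 0):
            raise ValueError("all concentration entries must be > 0")
        if self.poisson_scale_b is not None and not self.poisson_scale_b > 0:
            raise ValueError("poisson_scale_b must be > 0")
        object.__setattr__(self, "concentration", arr)
        arr.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.concentration.shape

    @property
    def scalar_a(self) -> float | None:
        """The common cell concentration, or None if cells differ."""
        a0 = float(self.concentration.flat[0])
        return a0 if np.all(self.concentration == a0) else None

    @property
    def is_uniform_unit(self) -> bool:
        """True when every ``a_rc`` equals 1 (the closed forms require this)."""
        return self.scalar_a == 1.0

    def row_sums(self) -> np.ndarray:
        return self.concentration.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.concentration.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.concentration.sum())


@dataclass(frozen=True)
class XiQuantities:
    """Margin-adjusted prior totals.

    ``xi_row = a_r. - (C-1)``, ``xi_col = a_.c - (R-1)`` and
    ``xi_total = a.. - (R-1)(C-1)``; with ``a = 1`` on a 2x2 table these are
    (1, 1), (1, 1) and 3.
    """

    xi_row: np.ndarray
    xi_col: np.ndarray
    xi_total: float


def default_prior(
    R: int, C: int, a: float = 1.0, grand_total: int | None = None,
    b: float | None = None,
) -> PriorSpec:
    """Uniform prior with every cell concentration equal to ``a``.

    When ``grand_total`` is given (and ``b`` is not), the Poisson gamma scale
    takes its default value ``b = R*C*a / grand_total``.
    """
    if not a > 0:
        raise ValueError(f"concentration a must be > 0, got {a}")
    if R < 2 or C < 2:
        raise ValueError("prior shape needs R >= 2 and C >= 2")
    if b is None and grand_total is not None:
        if grand_total < 1:
            raise ValueError("grand_total must be >= 1")
        b = R * C * a / grand_total
    return PriorSpec(np.full((R, C), float(a)), poisson_scale_b=b)


def prior_for_table(table, a: float = 1.0, b: float | None = None) -> PriorSpec:
    """Default prior matched to a table's shape and grand total."""
    R, C = table.shape
    return default_prior(R, C, a=a, grand_total=table.grand_total, b=b)


def xi_quantities(prior: PriorSpec, R: int | None = None, C: int | None = None) -> XiQuantities:
    """The xi quantities derived from a concentration matrix."""
    pr, pc = prior.shape
    if (R is not None and R != pr) or (C is not None and C != pc):
        raise ValueError(f"prior shape {prior.shape} does not match ({R},{C})")
    R, C = pr, pc
    return XiQuantities(
        xi_row=prior.row_sums() - (C - 1),
        xi_col=prior.col_sums() - (R - 1),
        xi_total=prior.total - (R - 1) * (C - 1),
    )


def log_dirichlet(vec) -> float:
    """Natural log of the Dirichlet function D(v) = prod Gamma(v_i) / Gamma(sum v_i).

    Accepts any positive vector or matrix (matrices are flattened; the
    normalizing Gamma always uses the sum of all entries).  The same function
    applies to full cell matrices and to margin vectors.
    """
    v = np.asarray(vec, dtype=float).ravel()
    if v.size == 0 or not np.all(v > 0):
        raise ValueError("log_dirichlet requires a non-empty vector of positive entries")
    return float(gammaln(v).sum() - gammaln(v.sum()))
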