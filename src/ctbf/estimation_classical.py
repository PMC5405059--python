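"""Posterior log-odds-ratio estimation and classical comparators.

The Bayes factors answer "is there an association?"; this module answers
"how strong is it?".  For a 2x2 table the association is summarized by the
log odds ratio ``log(y11 y22 / (y12 y21))``.  Its posterior is sampled
directly from the conjugate forms — a single Dirichlet over all four cells
(joint multinomial) or two independent betas (independent multinomial) — and
summarized by the median and the central 95% percentile interval.  Alongside
it sit the frequentist staples reported with every example: the Pearson
chi-square test (no continuity correction) and the Wald interval for the log
odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import ContingencyTable, TableShapeError

__all__ = [
    "PosteriorSummary",
    "ClassicalResult",
    "sample_log_odds_ratio",
    "pearson_chi_square",
    "classical_log_odds_ratio",
]

#: z-quantile for the conventional 95% Wald interval.
_Z95 = 1.96


@dataclass(frozen=True)
class PosteriorSummary:
    """Monte-Carlo summary of the posterior log odds ratio."""

    n_draws: int
    seed: int
    median_log_or: float
    ci95_log_or: tuple[float, float]
    scheme: str
    draws: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "median_log_or": self.median_log_or,
            "ci95_log_or": list(self.ci95_log_or),
        }


@dataclass(frozen=True)
class ClassicalResult:
    """Frequentist test and estimate fields (unused fields stay None)."""

    chi2: float | None = None
    df: int | None = None
    p_value: float | None = None
    log_or: float | None = None
    wald_ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "log_or": self.log_or,
            "wald_ci95": None if self.wald_ci95 is None else list(self.wald_ci95),
        }


def sample_log_odds_ratio(
    table: ContingencyTable,
    scheme: str = "independent_multinomial",
    a: float = 1.0,
    n_draws: int = 100_000,
    seed: int = 0,
    fixed_margin: str = "rows",
    keep_draws: bool = False,
) -> PosteriorSummary:
    """Sample the posterior of the 2x2 log odds ratio from its conjugate form.

    joint multinomial
        cell probabilities ~ Dirichlet(y + a); log OR = log(p11 p22 / (p12 p21)).
    independent multinomial
        per-group rates theta_i ~ Beta(y_i1 + a, y_i2 + a); log OR =
        logit(theta_1) - logit(theta_2).

    Summaries are reproducible bit-for-bit given (seed, n_draws).
    """
    if table.shape != (2, 2):
        raise TableShapeError("log-odds-ratio posterior requires a 2x2 table")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for stable quantiles")
    from .bayes_factors import SCHEMES

    scheme = SCHEMES.get(scheme, scheme)
    rng = np.random.default_rng(seed)
    if scheme == "joint_multinomial":
        alpha = (table.counts + a).ravel()
        p = rng.dirichlet(alpha, size=n_draws)
        log_or = np.log(p[:, 0] * p[:, 3] / (p[:, 1] * p[:, 2]))
    elif scheme == "independent_multinomial":
        t = table if fixed_margin == "rows" else table.transposed()
        y = t.counts
        th1 = rng.beta(y[0, 0] + a, y[0, 1] + a, size=n_draws)
        th2 = rng.beta(y[1, 0] + a, y[1, 1] + a, size=n_draws)
        log_or = np.log(th1 / (1 - th1)) - np.log(th2 / (1 - th2))
    else:
        raise ValueError(
            "posterior sampling supports the joint or independent multinomial "
            f"schemes, got {scheme!r}"
        )
    lo, med, hi = np.percentile(log_or, [2.5, 50.0, 97.5])
    return PosteriorSummary(
        n_draws=n_draws,
        seed=seed,
        median_log_or=float(med),
        ci95_log_or=(float(lo), float(hi)),
        scheme=scheme,
        draws=log_or if keep_draws else None,
    )


def pearson_chi_square(table: ContingencyTable) -> ClassicalResult:
    """Pearson chi-square test of independence, without continuity correction.

    Expected counts are ``row total * column total / grand total``; a zero
    row or column margin makes an expected count zero and raises.
    """
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise ValueError("chi-square test undefined: a zero margin gives expected count 0")
    res = stats.chi2_contingency(table.counts, correction=False)
    return ClassicalResult(chi2=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue))


def classical_log_odds_ratio(table: ContingencyTable) -> ClassicalResult:
    """Sample log odds ratio of a 2x2 table with its 95% Wald interval.

    No zero-cell (continuity) correction is applied; any zero cell raises.
    """
    if table.shape != (2, 2):
        raise TableShapeError("the odds ratio is defined for 2x2 tables")
    y = table.counts.astype(float)
    if (y == 0).any():
        raise ValueError(
            "zero cell count: the uncorrected log odds ratio is undefined "
            "(continuity corrections are out of scope)"
        )
    log_or = float(np.log(y[0, 0] * y[1, 1] / (y[0, 1] * y[1, 0])))
    se = float(np.sqrt((1.0 / y).sum()))
    return ClassicalResult(
        log_or=log_or, wald_ci95=(log_or - _Z95 * se, log_or + _Z95 * se)
    )
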