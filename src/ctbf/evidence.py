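"""Evidence interpretation, scaling experiments, and synthetic tables.

Bayes factors are continuous evidence; the conventional descriptive bins
(anecdotal / moderate / strong / very strong / extreme, with cut points 3,
10, 30, 100 and their reciprocals) are provided purely as communication
aids.  This module also reproduces the cell-scaling experiments — multiply
every cell of a base 2x2 table by c = 1..c_max and track each scheme's log
Bayes factor — and generates random tables faithful to each sampling
scheme's design constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes_factors as bf
from .priors import prior_for_table
from .tables import ContingencyTable, make_table

__all__ = [
    "EvidenceCategory",
    "CATEGORY_BOUNDS",
    "posterior_probability_from_bf",
    "jeffreys_category",
    "ScalingExperiment",
    "scaling_experiment",
    "generate_table",
]

#: Category boundaries on the BF10 scale.
CATEGORY_BOUNDS = (1 / 100, 1 / 30, 1 / 10, 1 / 3, 1.0, 3.0, 10.0, 30.0, 100.0)

_STRENGTH = ("Anecdotal", "Moderate", "Strong", "Very strong", "Extreme")


@dataclass(frozen=True)
class EvidenceCategory:
    """A descriptive evidence bin with its BF10 interval."""

    label: str
    bf_interval: tuple[float, float]
    favored_model: str  # "M1", "M2", or "none"


def posterior_probability_from_bf(
    bf10: float | None = None,
    prior_odds: float = 1.0,
    log_bf10: float | None = None,
) -> float:
    """Posterior P(M1) given the Bayes factor and prior odds for M1.

    ``P(M1 | y) = prior_odds * BF10 / (prior_odds * BF10 + 1)``; under
    equipoise (prior odds 1) this is BF/(BF+1).  Computed stably from the
    log Bayes factor, so extreme BFs neither overflow nor round to 0/1
    prematurely.
    """
    if log_bf10 is None:
        if bf10 is None or not bf10 > 0:
            raise ValueError("bf10 must be a positive number")
        log_bf10 = math.log(bf10)
    if not prior_odds > 0:
        raise ValueError("prior_odds must be > 0")
    log_posterior_odds = log_bf10 + math.log(prior_odds)
    # p = odds/(1+odds) = 1/(1+exp(-log_odds))
    return float(1.0 / (1.0 + math.exp(-log_posterior_odds)))


def jeffreys_category(bf10: float | None = None, log_bf10: float | None = None) -> EvidenceCategory:
    """Descriptive evidence bin for a Bayes factor BF10.

    Bins above 1 are half-open ``[lower, upper)`` and mirrored below 1 as
    ``(lower, upper]``, so a BF sitting exactly on a printed cut point (3,
    10, ...) is assigned to the stronger-evidence side; BF10 = 1 alone maps
    to "No evidence".
    """
    if log_bf10 is None:
        if bf10 is None or not bf10 > 0:
            raise ValueError("bf10 must be a positive number")
        log_bf10 = math.log(bf10)
    if log_bf10 == 0.0:
        return EvidenceCategory("No evidence", (1.0, 1.0), "none")
    mirrored = log_bf10 < 0
    x = abs(log_bf10)
    uppers = (3.0, 10.0, 30.0, 100.0)
    lo, hi, strength = 1.0, math.inf, _STRENGTH[-1]
    for i, u in enumerate(uppers):
        if x < math.log(u):
            lo, hi, strength = (1.0 if i == 0 else uppers[i - 1]), u, _STRENGTH[i]
            break
    else:
        lo = uppers[-1]
    model = "M2" if mirrored else "M1"
    interval = (1.0 / hi, 1.0 / lo) if mirrored else (lo, hi)
    return EvidenceCategory(f"{strength} evidence for {model}", interval, model)


# ---------------------------------------------------------------------------
# Cell-scaling experiments
# ---------------------------------------------------------------------------

_ALL_SCHEMES = ("poisson", "joint_multinomial", "independent_multinomial", "hypergeometric")


@dataclass(frozen=True)
class ScalingExperiment:
    """Per-factor, per-scheme natural-log BF10 for scaled copies of a base table."""

    base_counts: np.ndarray
    factors: tuple[int, ...]
    results: pd.DataFrame  # columns: c, grand_total, scheme, log_bf10

    def pivot(self) -> pd.DataFrame:
        """One row per factor c, one column per scheme."""
        return self.results.pivot(index="c", columns="scheme", values="log_bf10")


def scaling_experiment(base, c_max: int = 30, a: float = 1.0) -> ScalingExperiment:
    """Scale each cell of a 2x2 base table by c = 1..c_max and track all four BFs.

    The independent multinomial factor is computed rows-fixed.  Every scheme
    is recomputed from scratch on each scaled table (including the
    hypergeometric enumeration, whose support grows only linearly for 2x2).
    """
    base_t = make_table(base)
    if base_t.shape != (2, 2):
        raise ValueError("scaling experiments are defined for 2x2 base tables")
    if c_max < 1:
        raise ValueError("c_max must be >= 1")
    rows = []
    for c in range(1, c_max + 1):
        t = make_table(base_t.counts * c)
        prior = prior_for_table(t, a=a)
        values = {
            "poisson": bf.logbf10_poisson(t, prior),
            "joint_multinomial": bf.logbf10_joint_multinomial(t, prior),
            "independent_multinomial": bf.logbf10_independent_multinomial(t, prior, "rows"),
            "hypergeometric": bf.logbf10_hypergeometric(t, prior),
        }
        for scheme in _ALL_SCHEMES:
            rows.append(
                {
                    "c": c,
                    "grand_total": t.grand_total,
                    "scheme": scheme,
                    "log_bf10": values[scheme],
                }
            )
    return ScalingExperiment(
        base_counts=base_t.counts,
        factors=tuple(range(1, c_max + 1)),
        results=pd.DataFrame(rows),
    )


def plot_scaling_experiment(experiment: ScalingExperiment, path=None):
    """Draw the log-BF10 curves per scheme (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for scheme, group in experiment.results.groupby("scheme"):
        ax.plot(group["c"], group["log_bf10"], marker=".", label=scheme)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("cell scaling factor c")
    ax.set_ylabel("ln BF10")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Scheme-faithful synthetic tables
# ---------------------------------------------------------------------------

def _check_probs(p, name):
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be non-negative and sum to 1 (tolerance 1e-9)")
    return p


def generate_table(scheme: str, params: dict, seed: int) -> ContingencyTable:
    """Draw a random table under a sampling scheme's design constraints.

    Parameters per scheme (all arrays at least 2x2 / length-2):

    - ``poisson``: ``rates`` — matrix of cell intensities.
    - ``joint_multinomial``: ``grand_total`` and ``probs`` (cell probability
      matrix); the drawn table has exactly that grand total.
    - ``independent_multinomial``: ``row_totals`` and ``probs`` (one
      probability vector per row); row margins are fixed exactly.
    - ``hypergeometric``: ``row_totals``, ``col_totals`` and optional odds
      ratio ``psi`` (2x2 only); the table is drawn from the noncentral
      hypergeometric law by enumeration-weighted sampling of the free cell.

    Degenerate all-zero draws (possible under the Poisson scheme with tiny
    rates) are redrawn, so the result is always a valid table.
    """
    rng = np.random.default_rng(seed)
    scheme = bf.SCHEMES.get(scheme, scheme)
    if scheme == "poisson":
        rates = np.asarray(params["rates"], dtype=float)
        if rates.ndim != 2 or np.any(rates < 0):
            raise ValueError("rates must be a non-negative matrix")
        counts = rng.poisson(rates)
        while counts.sum() == 0:
            counts = rng.poisson(rates)
        return make_table(counts)
    if scheme == "joint_multinomial":
        probs = _check_probs(params["probs"], "probs")
        total = int(params["grand_total"])
        flat = rng.multinomial(total, probs.ravel())
        return make_table(flat.reshape(probs.shape))
    if scheme == "independent_multinomial":
        row_totals = np.asarray(params["row_totals"], dtype=int)
        probs = np.asarray(params["probs"], dtype=float)
        if probs.shape[0] != row_totals.size:
            raise ValueError("need one probability vector per fixed row")
        rows = []
        for n_r, p_r in zip(row_totals, probs):
            p_r = _check_probs(p_r, "row probability vector")
            rows.append(rng.multinomial(int(n_r), p_r))
        return make_table(np.vstack(rows))
    if scheme == "hypergeometric":
        rt = np.asarray(params["row_totals"], dtype=int)
        ct = np.asarray(params["col_totals"], dtype=int)
        psi = float(params.get("psi", 1.0))
        if rt.size != 2 or ct.size != 2:
            raise ValueError("hypergeometric generation is defined for 2x2 margins")
        lo = max(0, int(rt[0]) - int(ct[1]))
        hi = min(int(rt[0]), int(ct[0]))
        support = np.arange(lo, hi + 1)
        weights = np.array(
            [bf.noncentral_hypergeometric_pmf(int(i), rt, ct, psi) for i in support]
        )
        y11 = int(rng.choice(support, p=weights / weights.sum()))
        counts = [
            [y11, int(rt[0]) - y11],
            [int(ct[0]) - y11, int(ct[1]) - (int(rt[0]) - y11)],
        ]
        return make_table(counts)
    raise ValueError(f"unknown scheme {scheme!r}")
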