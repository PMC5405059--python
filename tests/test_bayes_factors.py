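import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import ctbf
from ctbf import (
    EnumerationCapError,
    UnsupportedCombinationError,
    bayes_factor,
    closed_form_2x2,
    count_fixed_margin_tables,
    enumerate_fixed_margin_tables,
    logbf10_hypergeometric,
    logbf10_independent_multinomial,
    logbf10_joint_multinomial,
    logbf10_poisson,
    make_table,
    noncentral_hypergeometric_pmf,
)
from ctbf.priors import prior_for_table
import oracles


def _prior(t, **kw):
    return prior_for_table(t, **kw)


class TestWorkedExamples:
    """2x2 results published for these data sets, at default priors."""

    def test_bridges_independent_multinomial(self, bridges):
        lb = logbf10_independent_multinomial(bridges, _prior(bridges), "rows")
        assert math.exp(lb) == pytest.approx(5.31, abs=0.005)

    def test_dolls_independent_multinomial(self, dolls):
        lb = logbf10_independent_multinomial(dolls, _prior(dolls), "rows")
        assert lb == pytest.approx(23.03, abs=0.005)

    def test_siblings_hypergeometric(self, siblings):
        lb = logbf10_hypergeometric(siblings, _prior(siblings))
        assert math.exp(lb) == pytest.approx(0.39, abs=0.005)

    def test_scaled_table_poisson_and_hypergeometric(self):
        t = make_table([[30, 30], [20, 50]])
        assert math.exp(logbf10_poisson(t, _prior(t))) == pytest.approx(9.19, abs=0.005)
        assert math.exp(logbf10_hypergeometric(t, _prior(t))) == pytest.approx(3.04, abs=0.005)


class TestDerivedValues:
    """Small cases checked against exact rational arithmetic."""

    def test_poisson_small(self):
        t = make_table([[3, 3], [2, 5]])
        expected = oracles.bf10_poisson(t.counts)  # = 1.3459...
        assert math.exp(logbf10_poisson(t, _prior(t))) == pytest.approx(float(expected), rel=1e-12)
        assert float(expected) == pytest.approx(1.346, abs=5e-4)

    def test_joint_multinomial_small(self):
        t = make_table([[3, 3], [2, 5]])
        expected = oracles.bf10_joint_multinomial(t.counts)  # = 1.0725
        assert math.exp(logbf10_joint_multinomial(t, _prior(t))) == pytest.approx(
            float(expected), rel=1e-12
        )
        assert float(expected) == pytest.approx(1.073, abs=5e-4)

    def test_independent_multinomial_uniform_table(self):
        t = make_table([[1, 1], [1, 1]])
        lb = logbf10_independent_multinomial(t, _prior(t), "rows")
        assert math.exp(lb) == pytest.approx(5 / 6, rel=1e-12)

    def test_hypergeometric_identity_table(self):
        t = make_table([[1, 0], [0, 1]])
        assert logbf10_hypergeometric(t, _prior(t)) == pytest.approx(0.0, abs=1e-12)


class TestClosedFormEquivalence:
    """At a = 1 each 2x2 kernel equals its factorial closed form."""

    @pytest.mark.parametrize("scheme", ["poisson", "joint_multinomial",
                                        "independent_multinomial", "hypergeometric"])
    def test_random_tables(self, scheme):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            t = make_table(oracles.random_2x2(rng))
            prior = _prior(t)
            if scheme == "poisson":
                general = logbf10_poisson(t, prior)
            elif scheme == "joint_multinomial":
                general = logbf10_joint_multinomial(t, prior)
            elif scheme == "independent_multinomial":
                general = logbf10_independent_multinomial(t, prior, "rows")
            else:
                general = logbf10_hypergeometric(t, prior)
            assert general == pytest.approx(closed_form_2x2(t, scheme), rel=1e-9, abs=1e-9)

    def test_closed_form_requires_2x2(self):
        with pytest.raises(ctbf.TableShapeError):
            closed_form_2x2(make_table([[1, 2, 3], [4, 5, 6]]), "poisson")


class TestExactRationalOracle:
    """Log-gamma kernels agree with big-integer arithmetic for y.. <= 60."""

    def test_all_schemes(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            t = make_table(oracles.random_2x2(rng, cell_max=15))
            prior = _prior(t)
            checks = [
                (logbf10_poisson(t, prior), oracles.bf10_poisson(t.counts)),
                (logbf10_joint_multinomial(t, prior), oracles.bf10_joint_multinomial(t.counts)),
                (
                    logbf10_independent_multinomial(t, prior, "rows"),
                    oracles.bf10_independent_multinomial_rows(t.counts),
                ),
                (
                    logbf10_hypergeometric(t, prior),
                    oracles.bf10_eq17_min_margin(t.counts),
                ),
            ]
            for log_value, exact in checks:
                expected = math.log(exact.numerator) - math.log(exact.denominator)
                assert log_value == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_rectangular_table(self):
        t = make_table([[4, 1, 3], [2, 5, 0], [1, 2, 6]])
        prior = _prior(t)
        for log_value, exact in [
            (logbf10_poisson(t, prior), oracles.bf10_poisson(t.counts)),
            (logbf10_joint_multinomial(t, prior), oracles.bf10_joint_multinomial(t.counts)),
            (
                logbf10_independent_multinomial(t, prior, "rows"),
                oracles.bf10_independent_multinomial_rows(t.counts),
            ),
        ]:
            expected = math.log(exact.numerator) - math.log(exact.denominator)
            assert log_value == pytest.approx(expected, rel=1e-10, abs=1e-10)


class TestInvariances:
    def test_poisson_and_joint_multinomial_permutation_invariance(self):
        rng = np.random.default_rng(3)
        t = make_table(rng.integers(0, 9, size=(3, 4)))
        prior = _prior(t)
        base_p = logbf10_poisson(t, prior)
        base_m = logbf10_joint_multinomial(t, prior)
        variants = [
            t.counts[::-1],           # row permutation
            t.counts[:, ::-1],        # column permutation
            t.counts.T,               # transposition
            t.counts[[2, 0, 1]][:, [3, 1, 0, 2]],
        ]
        for counts in variants:
            v = make_table(counts)
            pv = _prior(v)
            assert logbf10_poisson(v, pv) == pytest.approx(base_p, rel=1e-12, abs=1e-12)
            assert logbf10_joint_multinomial(v, pv) == pytest.approx(base_m, rel=1e-12, abs=1e-12)

    def test_independent_multinomial_within_margin_permutations(self):
        t = make_table([[4, 1, 3], [2, 5, 0]])
        base = logbf10_independent_multinomial(t, _prior(t), "rows")
        swapped_rows = make_table(t.counts[::-1])
        swapped_cols = make_table(t.counts[:, [2, 0, 1]])
        for v in (swapped_rows, swapped_cols):
            assert logbf10_independent_multinomial(v, _prior(v), "rows") == pytest.approx(
                base, rel=1e-12
            )

    def test_columns_fixed_equals_rows_fixed_on_transpose(self, bridges):
        by_columns = logbf10_independent_multinomial(bridges, _prior(bridges), "columns")
        tt = bridges.transposed()
        by_rows = logbf10_independent_multinomial(tt, _prior(tt), "rows")
        assert by_columns == pytest.approx(by_rows, rel=1e-14)


class TestRatioIdentities:
    """Algebraic ratios between the four factors on 2x2 tables at a = 1.

    The orientation conventions were resolved by brute force against the
    exact-rational oracles: the Poisson/joint-multinomial ratio is
    orientation-free; the Poisson/independent ratio uses the two fixed
    (row) margins; ratios against the hypergeometric factor hold with the
    *smallest* margin in the distinguished position, matching the
    min-margin form of the factorial closed form.
    """

    def test_poisson_over_joint_multinomial(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            t = make_table(oracles.random_2x2(rng))
            n = t.grand_total
            ratio = math.exp(
                logbf10_poisson(t, _prior(t)) - logbf10_joint_multinomial(t, _prior(t))
            )
            assert ratio == pytest.approx(4 * (n + 3) / (3 * (n + 4)), rel=1e-10)

    def test_poisson_over_joint_multinomial_on_bridges(self, bridges):
        ratio = math.exp(
            logbf10_poisson(bridges, _prior(bridges))
            - logbf10_joint_multinomial(bridges, _prior(bridges))
        )
        assert ratio == pytest.approx(1.298, abs=5e-4)

    def test_poisson_over_independent_uses_fixed_margins(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = make_table(oracles.random_2x2(rng, cell_max=12))
            exact = oracles.bf10_poisson(t.counts) / oracles.bf10_independent_multinomial_rows(
                t.counts
            )
            n = t.grand_total
            r1, r2 = (int(v) for v in t.row_totals)
            assert exact == Fraction(8 * (r1 + 1) * (r2 + 1), (n + 4) * (n + 2))

    def test_poisson_over_hypergeometric_uses_min_margin(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            t = make_table(oracles.random_2x2(rng, cell_max=12))
            exact = oracles.bf10_poisson(t.counts) / oracles.bf10_eq17_min_margin(t.counts)
            n = t.grand_total
            m = min(int(t.row_totals.min()), int(t.col_totals.min()))
            assert exact == Fraction(8 * (n + 1) * (m + 1), (n + 4) * (n + 2))

    def test_independent_over_hypergeometric_when_min_margin_is_fixed_row(self):
        rng = np.random.default_rng(44)
        checked = 0
        for _ in range(200):
            t = make_table(oracles.random_2x2(rng, cell_max=12))
            r1, r2 = (int(v) for v in t.row_totals)
            m = min(int(t.row_totals.min()), int(t.col_totals.min()))
            if r1 != m or r2 == m:
                continue
            exact = oracles.bf10_independent_multinomial_rows(
                t.counts
            ) / oracles.bf10_eq17_min_margin(t.counts)
            assert exact == Fraction(t.grand_total + 1, r2 + 1)
            checked += 1
        assert checked > 20

    def test_poisson_always_exceeds_joint_multinomial(self):
        rng = np.random.default_rng(45)
        for _ in range(100):
            t = make_table(oracles.random_2x2(rng))
            assert logbf10_poisson(t, _prior(t)) > logbf10_joint_multinomial(t, _prior(t))


class TestEnumeration:
    @pytest.mark.parametrize(
        "rows, cols, expected",
        [
            ([1, 1], [1, 1], 2),
            ([15, 15], [15, 15], 16),
            ([2, 1], [1, 1, 1], 3),
        ],
    )
    def test_counts(self, rows, cols, expected):
        assert count_fixed_margin_tables(rows, cols) == expected

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            shape = rng.choice([(2, 2), (2, 3), (3, 3)])
            t = rng.integers(0, 4, size=tuple(shape))
            rows, cols = t.sum(axis=1), t.sum(axis=0)
            ours = sorted(
                tuple(x.ravel()) for x in enumerate_fixed_margin_tables(rows, cols)
            )
            brute = sorted(
                tuple(np.asarray(x).ravel())
                for x in oracles.brute_force_fixed_margin_tables(rows, cols)
            )
            assert ours == brute

    def test_each_table_has_requested_margins(self):
        for t in enumerate_fixed_margin_tables([4, 3], [2, 2, 3]):
            assert t.sum(axis=1).tolist() == [4, 3]
            assert t.sum(axis=0).tolist() == [2, 2, 3]

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            list(enumerate_fixed_margin_tables([2, 2], [1, 1]))

    def test_enumeration_cap(self, siblings):
        with pytest.raises(EnumerationCapError, match="closed form"):
            logbf10_hypergeometric(siblings, _prior(siblings), enumeration_cap=5)

    def test_sum_form_equals_min_margin_closed_form(self):
        """The fixed-margin sum collapses to the factorial closed form (a=1)."""
        rng = np.random.default_rng(10)
        for _ in range(60):
            t = make_table(oracles.random_2x2(rng, cell_max=10))
            assert logbf10_hypergeometric(t, _prior(t)) == pytest.approx(
                closed_form_2x2(t, "hypergeometric"), rel=1e-9, abs=1e-9
            )


class TestNoncentralHypergeometric:
    def test_central_example(self):
        p = noncentral_hypergeometric_pmf(9, [18, 16], [11, 23], psi=1.0)
        assert p == pytest.approx(float(oracles.central_hypergeometric_pmf(9, [18, 16], [11, 23])),
                                  rel=1e-12)
        assert p == pytest.approx(0.0204, abs=5e-5)

    def test_tiny_noncentral_value(self):
        assert noncentral_hypergeometric_pmf(1, [1, 1], [1, 1], psi=2.0) == pytest.approx(2 / 3)

    def test_normalization_and_psi1_reduction(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = oracles.random_2x2(rng, cell_max=15)
            rows, cols = t.sum(axis=1), t.sum(axis=0)
            psi = float(rng.uniform(0.2, 5.0))
            lo = max(0, rows[0] - cols[1])
            hi = min(rows[0], cols[0])
            total = sum(
                noncentral_hypergeometric_pmf(i, rows, cols, psi) for i in range(lo, hi + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)
            central = noncentral_hypergeometric_pmf(hi, rows, cols, 1.0)
            assert central == pytest.approx(
                stats.hypergeom.pmf(hi, rows.sum(), cols[0], rows[0]), rel=1e-9
            )

    def test_matches_scipy_fisher_noncentral(self):
        rows, cols, psi = [18, 16], [11, 23], 2.5
        dist = stats.nchypergeom_fisher(sum(rows), cols[0], rows[0], psi)
        for y11 in range(0, 12):
            assert noncentral_hypergeometric_pmf(y11, rows, cols, psi) == pytest.approx(
                float(dist.pmf(y11)), rel=1e-9, abs=1e-12
            )

    def test_out_of_support_is_zero(self):
        assert noncentral_hypergeometric_pmf(12, [18, 16], [11, 23], 1.0) == 0.0


class TestDispatcher:
    def test_matches_kernel(self, siblings):
        res = bayes_factor(siblings, "poisson")
        assert res.log_bf10 == logbf10_poisson(siblings, res.prior)
        assert res.fixed_margin == "none" and res.direction == "two_sided"

    def test_onesided_bridges(self, bridges):
        # exact finite-sum evaluation gives 10.509; the published 10.50 stems
        # from applying the correction to the 2-d.p. two-sided factor 5.31
        res = bayes_factor(bridges, "indepmn", fixed_margin="rows", direction="greater")
        assert res.bf10 == pytest.approx(10.50, abs=0.01)

    def test_siblings_favor_null(self, siblings):
        res = bayes_factor(siblings, "hypergeom")
        assert res.bf01 == pytest.approx(2.56, abs=0.05)
        assert res.evidence_category.favored_model == "M2"

    def test_result_derived_quantities(self, bridges):
        res = bayes_factor(bridges, "jointmn")
        assert res.log_bf01 == -res.log_bf10
        assert res.bf01 == pytest.approx(1 / res.bf10, rel=1e-12)
        assert res.posterior_prob_h1 == pytest.approx(res.bf10 / (res.bf10 + 1), rel=1e-12)

    def test_direction_unsupported_outside_indepmn_2x2(self, bridges, occupations):
        with pytest.raises(UnsupportedCombinationError):
            bayes_factor(bridges, "poisson", direction="greater")
        with pytest.raises(UnsupportedCombinationError):
            bayes_factor(occupations, "indepmn", direction="greater")

    def test_prior_shape_mismatch(self, bridges, occupations):
        res = bayes_factor(occupations, "jointmn")
        with pytest.raises(ValueError, match="shape"):
            logbf10_joint_multinomial(bridges, res.prior)

    def test_nonunit_concentration_supported(self, bridges):
        strong = bayes_factor(bridges, "jointmn", a=10.0)
        weak = bayes_factor(bridges, "jointmn", a=1.0)
        # larger a pulls H1's predictions toward H0's: evidence for H1 shrinks
        assert strong.log_bf10 < weak.log_bf10
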