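"""Exact inference engine vs arbitrary-precision oracles and scipy/R conventions.

Expected numeric values for the printed 2x2 tables were computed with this
model and cross-checked against R ``fisher.test`` (conditional MLE, exact CI,
probability-mass-ordering p) and ``scipy.stats.contingency.odds_ratio``.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact, hypergeom
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from sacts_kit.exact import (
    DegenerateTableError,
    EnumerationCapExceeded,
    Table2x2,
    TableRxC,
    cmle_odds_ratio,
    crude_odds_ratio,
    exact_or_ci,
    exact_test_2x2,
    fisher_2x2,
    fisher_rxc,
    nchg_pmf,
)

from oracles import fisher_2x2_exact, fisher_rxc_exact, nchg_pmf_exact

cells = st.integers(min_value=0, max_value=40)


def random_tables(n, seed, max_cell=60, min_margin=1):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        t = Table2x2(*(int(v) for v in rng.integers(0, max_cell + 1, 4)))
        (r1, r2), (c1, c2) = t.margins
        if min(r1, r2, c1, c2) >= min_margin:
            out.append(t)
    return out


class TestNchgPmf:
    def test_central_case_matches_hypergeom(self):
        m, n, k = 12, 9, 10
        for x in range(0, 11):
            assert nchg_pmf(x, m, n, k, 1.0) == pytest.approx(
                hypergeom.pmf(x, m + n, m, k), rel=1e-12, abs=1e-15
            )

    @pytest.mark.parametrize("psi", [0.1, 1.0, 10.0])
    def test_normalizes_over_support(self, psi):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m, n = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            k = int(rng.integers(1, m + n))
            total = sum(nchg_pmf(x, m, n, k, psi) for x in range(0, k + 1))
            assert total == pytest.approx(1.0, rel=1e-10)

    def test_matches_exact_rational_arithmetic(self):
        val = nchg_pmf(3, 5, 5, 5, 2.0)
        exact = nchg_pmf_exact(3, 5, 5, 5, Fraction(2))
        assert val == pytest.approx(float(exact), rel=1e-12)
        # and across a whole small support at an awkward psi
        for x in range(0, 7):
            assert nchg_pmf(x, 6, 8, 7, 0.37) == pytest.approx(
                float(nchg_pmf_exact(x, 6, 8, 7, Fraction(37, 100))), rel=1e-10
            )

    def test_outside_support_is_zero_and_negative_psi_rejected(self):
        assert nchg_pmf(6, 5, 5, 5, 1.0) == 0.0
        assert nchg_pmf(-1, 5, 5, 5, 1.0) == 0.0
        with pytest.raises(ValueError):
            nchg_pmf(2, 5, 5, 5, -0.5)

    def test_psi_zero_concentrates_at_support_minimum(self):
        assert nchg_pmf(2, 5, 5, 7, 0.0) == 1.0  # support minimum is max(0, 7-5)
        assert nchg_pmf(3, 5, 5, 7, 0.0) == 0.0


class TestFisher2x2:
    def test_balanced_table_p_is_one(self):
        assert fisher_2x2(Table2x2(5, 5, 5, 5)) == 1.0

    def test_printed_association_p_values(self, printed_tables):
        for spec in printed_tables.values():
            if spec["p3"] is not None:
                p = fisher_2x2(Table2x2.from_rows(spec["rows"]))
                assert round(p, 3) == spec["p3"]

    def test_orientation_invariance_of_bilateral_table(self):
        """p is unchanged when the table is given critical-rows-first."""
        assert fisher_2x2(Table2x2(90, 9, 197, 5)) == pytest.approx(
            fisher_2x2(Table2x2(197, 90, 5, 9)), rel=1e-12
        )

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=150, derandomize=True)
    def test_transposition_invariance(self, a, b, c, d):
        t = Table2x2(a, b, c, d)
        transposed = Table2x2(a, c, b, d)
        assert fisher_2x2(t) == pytest.approx(fisher_2x2(transposed), rel=1e-9, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        for t in random_tables(50, seed=1):
            assert fisher_2x2(t) == pytest.approx(
                fisher_exact(t.rows)[1], rel=1e-9, abs=1e-12
            )

    def test_matches_integer_oracle_on_random_tables(self):
        for t in random_tables(50, seed=2, max_cell=15, min_margin=0):
            assert fisher_2x2(t) == pytest.approx(
                float(fisher_2x2_exact(t.a, t.b, t.c, t.d)), rel=1e-10, abs=1e-12
            )

    def test_zero_margin_gives_p_one(self):
        assert fisher_2x2(Table2x2(0, 0, 3, 4)) == 1.0


class TestCmleOddsRatio:
    def test_printed_odds_ratios(self, printed_tables):
        for name, spec in printed_tables.items():
            value = cmle_odds_ratio(Table2x2.from_rows(spec["rows"]))
            assert round(value, 2) == spec["odds_ratio"], name

    @pytest.mark.parametrize("x", [1, 4, 17])
    def test_symmetric_table_gives_one(self, x):
        assert cmle_odds_ratio(Table2x2(x, x, x, x)) == pytest.approx(1.0, abs=1e-9)

    def test_self_consistency_expected_cell_equals_observed(self):
        from sacts_kit.exact import _conditional_dist

        for t in random_tables(30, seed=3, max_cell=25):
            psi = cmle_odds_ratio(t)
            if psi in (0.0, math.inf):
                continue
            support, probs = _conditional_dist(t, math.log(psi))
            assert float((support * probs).sum()) == pytest.approx(t.a, abs=1e-6)

    def test_matches_scipy_conditional_estimate(self):
        for t in random_tables(30, seed=4, max_cell=30):
            ours = cmle_odds_ratio(t)
            ref = scipy_odds_ratio(t.rows, kind="conditional").statistic
            if math.isinf(ours):
                assert math.isinf(ref) or ref > 1e6
            else:
                assert ours == pytest.approx(ref, rel=1e-6, abs=1e-9)

    def test_boundary_cells(self):
        assert cmle_odds_ratio(Table2x2(0, 5, 3, 4)) == 0.0
        assert cmle_odds_ratio(Table2x2(5, 0, 3, 4)) == math.inf

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateTableError, match="row"):
            cmle_odds_ratio(Table2x2(0, 0, 3, 4))

    def test_cmle_weakly_closer_to_one_than_crude(self):
        for t in random_tables(40, seed=5, max_cell=30, min_margin=1):
            if t.a * t.b * t.c * t.d == 0:
                continue
            cmle, crude = cmle_odds_ratio(t), crude_odds_ratio(t)
            assert (cmle - 1) * (crude - 1) >= -1e-9  # same side of 1
            assert abs(math.log(cmle)) <= abs(math.log(crude)) + 1e-9


class TestCrudeOddsRatio:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[199, 70], [3, 29]], 27.48),
            ([[1, 1], [1, 1]], 1.0),
            ([[138, 50], [64, 49]], 2.11),
        ],
    )
    def test_values(self, rows, expected):
        assert round(crude_odds_ratio(Table2x2.from_rows(rows)), 2) == expected

    def test_zero_denominator_is_infinite(self):
        assert crude_odds_ratio(Table2x2(3, 0, 2, 4)) == math.inf


class TestExactOrCi:
    def test_printed_confidence_intervals(self, printed_tables):
        for name, spec in printed_tables.items():
            lo, hi = exact_or_ci(Table2x2.from_rows(spec["rows"]), 0.95)
            assert (round(lo, 2), round(hi, 2)) == spec["ci"], name

    def test_matches_scipy_exact_ci(self):
        for t in random_tables(15, seed=6, max_cell=25):
            lo, hi = exact_or_ci(t, 0.95)
            ref = scipy_odds_ratio(t.rows, kind="conditional").confidence_interval(0.95)
            assert lo == pytest.approx(ref.low, rel=1e-6, abs=1e-9)
            if math.isinf(hi):
                assert math.isinf(ref.high)
            else:
                assert hi == pytest.approx(ref.high, rel=1e-6)

    def test_boundary_conventions(self):
        lo, hi = exact_or_ci(Table2x2(0, 5, 3, 4), 0.95)
        assert lo == 0.0 and hi < math.inf
        lo, hi = exact_or_ci(Table2x2(5, 0, 3, 4), 0.95)
        assert lo > 0.0 and hi == math.inf

    def test_nesting_and_bracketing(self):
        for t in random_tables(15, seed=7, max_cell=20):
            if t.a * t.b * t.c * t.d == 0:
                continue
            lo95, hi95 = exact_or_ci(t, 0.95)
            lo99, hi99 = exact_or_ci(t, 0.99)
            assert lo99 < lo95 and hi99 > hi95
            psi = cmle_odds_ratio(t)
            assert lo95 <= psi <= hi95

    def test_invalid_conf_level(self):
        with pytest.raises(ValueError):
            exact_or_ci(Table2x2(5, 5, 5, 5), 1.5)


class TestExactTestBundle:
    def test_result_fields_consistent(self, printed_tables):
        res = exact_test_2x2(Table2x2.from_rows(printed_tables["ccts_high"]["rows"]))
        assert 0 <= res.p_two_sided <= 1
        assert res.ci_low <= res.or_cmle <= res.ci_high
        assert res.estimate_kind == "conditional_mle"


class TestFisherRxc:
    def test_age_3x2_p_value(self):
        """Three age bands vs outcome: p = 0.060 at 3 dp."""
        p = fisher_rxc([[148, 81], [44, 11], [10, 7]])
        assert round(p, 3) == 0.060

    def test_2x2_specialization_matches_fisher_2x2(self, printed_tables):
        for spec in printed_tables.values():
            t = Table2x2.from_rows(spec["rows"])
            assert fisher_rxc(spec["rows"]) == pytest.approx(fisher_2x2(t), abs=1e-12)

    def test_random_3x2_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        done = 0
        while done < 25:
            rows = rng.integers(0, 6, size=(3, 2))
            if rows.sum() > 15 or rows.sum() == 0:
                continue
            if min(rows.sum(axis=0)) == 0 or min(rows.sum(axis=1)) == 0:
                continue
            p = fisher_rxc(rows.tolist())
            assert p == pytest.approx(float(fisher_rxc_exact(rows.tolist())), rel=1e-10)
            done += 1

    def test_all_zero_row_is_dropped_not_degenerate(self):
        with_empty = fisher_rxc([[184, 75], [18, 23], [0, 0]])
        without = fisher_rxc([[184, 75], [18, 23]])
        assert with_empty == pytest.approx(without, abs=1e-12)

    def test_enumeration_cap(self):
        with pytest.raises(EnumerationCapExceeded):
            fisher_rxc([[30, 30, 30], [30, 30, 30], [30, 30, 30]], max_tables=100)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            TableRxC.from_rows([[1, 2]])
        with pytest.raises(ValueError):
            TableRxC.from_rows([[1], [2]])
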