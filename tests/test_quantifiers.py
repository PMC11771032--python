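"""Four-fold tables and both generalized quantifiers, against oracles."""

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, strategies as strat

from _oracles import fisher_tail_exact
from guhapaths.errors import DegenerateTableError, ValidationError
from guhapaths.quantifiers import (
    FourFoldTable,
    QuantifierConfig,
    above_average_truth,
    build_table,
    fisher_pvalue,
    fisher_truth,
    frequency_coefficient,
)

cells = strat.integers(min_value=0, max_value=60)


class TestBuildTable:
    def test_direct_count(self):
        t = build_table([[True, True, False, False]], [True, False, True, False])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_conjunction_then_count(self):
        t = build_table(
            [[True, True, False, False], [True, False, True, False]],
            [True, True, True, True],
        )
        assert (t.a, t.b, t.c, t.d) == (1, 0, 3, 0)

    def test_all_false_antecedent(self):
        t = build_table([[False] * 5], [True, True, False, False, False])
        assert t.a == 0 and t.b == 0 and t.c + t.d == 5

    def test_empty_antecedent_rejected(self):
        with pytest.raises(ValidationError):
            build_table([], [True, False])

    def test_conserves_m_and_margins(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            cols = [rng.random(n) < 0.5 for _ in range(3)]
            psi = rng.random(n) < 0.3
            t = build_table(cols, psi)
            assert t.m == n and t.r + t.s == t.k + t.l == t.m

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(11)
        col, psi = rng.random(40) < 0.5, rng.random(40) < 0.4
        perm = rng.permutation(40)
        assert build_table([col], psi) == build_table([col[perm]], psi[perm])


class TestAboveAverage:
    def test_boundary_equality_is_true(self):
        # confidence 0.5 is exactly (1+4) times prevalence 0.1
        t = FourFoldTable(10, 10, 90, 890)
        assert above_average_truth(t, QuantifierConfig(p=4, base=10)) is True

    def test_lift_below_threshold_is_false(self):
        # lift 0.5 / 0.15 = 10/3 < 5
        t = FourFoldTable(50, 50, 100, 800)
        assert above_average_truth(t, QuantifierConfig(p=4, base=10)) is False

    def test_support_below_base_is_false(self):
        t = FourFoldTable(9, 1, 10, 980)  # huge lift but a < base
        assert above_average_truth(t, QuantifierConfig(p=1, base=10)) is False

    def test_empty_antecedent_is_false(self):
        t = FourFoldTable(0, 0, 10, 90)
        assert above_average_truth(t, QuantifierConfig(p=0.5, base=1)) is False

    @given(cells, cells, cells, cells)
    def test_monotone_in_p_and_base(self, a, b, c, d):
        t = FourFoldTable(a, b, c, d)
        if t.m == 0:
            return
        for p_small, p_big in [(0.2, 0.5), (0.5, 2.0)]:
            if above_average_truth(t, QuantifierConfig(p=p_big, base=3)):
                assert above_average_truth(t, QuantifierConfig(p=p_small, base=3))
        if above_average_truth(t, QuantifierConfig(p=1, base=8)):
            assert above_average_truth(t, QuantifierConfig(p=1, base=2))


class TestFrequencyCoefficient:
    def test_five_fold_lift(self):
        assert frequency_coefficient(FourFoldTable(10, 10, 90, 890)) == pytest.approx(4.0)

    def test_no_excess_over_average(self):
        assert frequency_coefficient(FourFoldTable(25, 75, 225, 675)) == pytest.approx(0.0)

    def test_coefficient_one_means_twice_as_common(self):
        # confidence 0.4 vs prevalence 0.2: the outcome is 2x as common
        t = FourFoldTable(40, 60, 60, 340)
        assert frequency_coefficient(t) == pytest.approx(1.0)

    def test_degenerate_margins_signalled(self):
        with pytest.raises(DegenerateTableError):
            frequency_coefficient(FourFoldTable(0, 0, 5, 5))
        with pytest.raises(DegenerateTableError):
            frequency_coefficient(FourFoldTable(0, 5, 0, 5))

    @given(cells, cells, cells, cells, strat.floats(min_value=0.05, max_value=3))
    def test_coefficient_is_threshold_of_truth(self, a, b, c, d, p):
        """fc >= p iff the quantifier holds at that p with base 1."""
        t = FourFoldTable(a, b, c, d)
        if t.r == 0 or t.k == 0 or t.a == 0:
            return
        fc = frequency_coefficient(t)
        if abs(fc - p) < 1e-9:  # knife-edge: float equality undecidable
            return
        assert (fc >= p) == above_average_truth(t, QuantifierConfig(p=p, base=1))


class TestFisher:
    def test_extreme_table_exact_value(self):
        # C(10,5) = 252 tables, only one with A = 5
        assert fisher_pvalue(FourFoldTable(5, 0, 0, 5)) == pytest.approx(
            1 / 252, abs=1e-12
        )

    def test_symmetric_small_table(self):
        # 1 - P(A=0) = 1 - 1/6
        assert fisher_pvalue(FourFoldTable(1, 1, 1, 1)) == pytest.approx(5 / 6)

    def test_no_succedent_rows_gives_one(self):
        assert fisher_pvalue(FourFoldTable(0, 10, 0, 30)) == 1.0

    def test_truth_requires_strict_positive_association(self):
        cfg = QuantifierConfig(p=1, base=1, alpha=0.5)
        assert fisher_truth(FourFoldTable(1, 1, 1, 1), cfg) is False  # ad == bc

    def test_truth_at_alpha(self):
        t = FourFoldTable(5, 0, 0, 5)
        assert fisher_truth(t, QuantifierConfig(p=1, base=1, alpha=0.01)) is True
        assert fisher_truth(t, QuantifierConfig(p=1, base=1, alpha=0.001)) is False

    @given(cells, cells, cells, cells)
    def test_matches_exact_enumeration(self, a, b, c, d):
        t = FourFoldTable(a, b, c, d)
        if t.m == 0:
            return
        assert fisher_pvalue(t) == pytest.approx(
            float(fisher_tail_exact(t)), abs=1e-12
        )

    def test_matches_scipy_one_sided(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            if a + b + c + d == 0:
                continue
            t = FourFoldTable(a, b, c, d)
            ref = st.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert fisher_pvalue(t) == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_large_counts_do_not_overflow(self):
        t = FourFoldTable(200_000, 100_000, 1_345_000, 4_612_000)
        p = fisher_pvalue(t)
        assert 0.0 <= p <= 1.0


def test_negative_cells_rejected():
    with pytest.raises(ValidationError):
        FourFoldTable(-1, 0, 0, 0)


def test_config_bounds():
    with pytest.raises(ValidationError):
        QuantifierConfig(p=0, base=1)
    with pytest.raises(ValidationError):
        QuantifierConfig(p=1, base=0)
    with pytest.raises(ValidationError):
        QuantifierConfig(p=1, base=1, alpha=0.6)
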