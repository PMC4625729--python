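"""Agreement statistics: classification rule, kappa, panel, AUC, sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ilaquant.agreement import (
    ContingencyTable2x2,
    DegenerateTableError,
    best_threshold,
    build_contingency,
    c_statistic,
    classify_by_haa,
    cohen_kappa,
    diagnostic_panel,
    percentile_threshold,
    threshold_sweep,
)

from conftest import make_cohort


class TestClassify:
    def test_boundary_is_positive(self):
        assert classify_by_haa(10.0, 10.0) is True
        assert classify_by_haa(9.999, 10.0) is False
        assert classify_by_haa(6.44, 6.44) is True

    def test_vectorized(self):
        out = classify_by_haa(np.array([1.0, 10.0, 20.0]), 10.0)
        assert out.tolist() == [False, True, True]

    @pytest.mark.parametrize("thr", [0.0, 100.0, -5.0, 120.0])
    def test_threshold_outside_open_interval_rejected(self, thr):
        with pytest.raises(ValueError, match="threshold"):
            classify_by_haa(5.0, thr)


class TestPercentile:
    def test_linear_interpolation_closed_form(self):
        # sorted 1..100: the 95th percentile sits at rank 1+99*0.95=95.05
        assert percentile_threshold(np.arange(1, 101), 95) == pytest.approx(95.05)

    def test_constant_values(self):
        assert percentile_threshold(np.full(50, 5.0), 95) == 5.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(1.2, 0.4, 200)
        assert percentile_threshold(vals, 95) == percentile_threshold(
            rng.permutation(vals), 95
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([], 95)


class TestContingency:
    def test_four_row_enumeration(self):
        cohort = make_cohort(
            [(12.0, "ila"), (4.0, "ila"), (13.0, "no_ila"), (3.0, "no_ila")]
        )
        t = build_contingency(cohort, 10.0, "exclude")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_indeterminate_policies(self, toy_cohort):
        excl = build_contingency(toy_cohort, 10.0, "exclude")
        asc = build_contingency(toy_cohort, 10.0, "as_control")
        assert excl.total == 6 and asc.total == 8
        # both indeterminates (7%, 6%) fall below 10% -> no-ILA negative row grows
        assert asc.d == excl.d + 2 and asc.c == excl.c
        assert asc.n_indeterminate_absorbed == 2

    def test_all_indeterminate_cohort_rejected_under_exclude(self):
        cohort = make_cohort([(5.0, "indeterminate"), (6.0, "indeterminate")])
        with pytest.raises(DegenerateTableError):
            build_contingency(cohort, 10.0, "exclude")


class TestKappa:
    def test_perfect_agreement(self):
        kap, _ = cohen_kappa(ContingencyTable2x2(50, 0, 0, 50))
        assert kap == pytest.approx(1.0)

    def test_independent_marginals_give_zero(self):
        # joint = product of marginals: rows (20,80)%, cols (50,50)%
        kap, p = cohen_kappa(ContingencyTable2x2(10, 10, 40, 40))
        assert kap == pytest.approx(0.0, abs=1e-12)

    def test_simultaneous_row_column_swap_symmetry(self):
        t1 = ContingencyTable2x2(12, 5, 9, 70)
        t2 = ContingencyTable2x2(70, 9, 5, 12)
        assert cohen_kappa(t1)[0] == pytest.approx(cohen_kappa(t2)[0])

    def test_degenerate_marginals_raise(self):
        with pytest.raises(DegenerateTableError, match="undefined"):
            cohen_kappa(ContingencyTable2x2(10, 0, 0, 0))

    @given(
        st.tuples(
            st.integers(0, 60), st.integers(0, 60),
            st.integers(0, 60), st.integers(0, 60),
        ).filter(lambda t: t[0] + t[1] > 0 and t[2] + t[3] > 0
                 and t[0] + t[2] > 0 and t[1] + t[3] > 0)
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_sklearn_oracle(self, counts):
        from sklearn.metrics import cohen_kappa_score

        a, b, c, d = counts
        y_vis = [1] * (a + b) + [0] * (c + d)
        y_haa = [1] * a + [0] * b + [1] * c + [0] * d
        try:
            kap, _ = cohen_kappa(ContingencyTable2x2(a, b, c, d))
        except DegenerateTableError:
            return
        assert kap == pytest.approx(cohen_kappa_score(y_vis, y_haa), abs=1e-10)


class TestPanel:
    def test_all_correct(self):
        s = diagnostic_panel(ContingencyTable2x2(10, 0, 0, 10))
        assert (s.sensitivity, s.specificity, s.ppv, s.npv) == (1, 1, 1, 1)

    def test_undefined_rates_are_missing_not_zero(self):
        # no positive predictions: PPV has a zero denominator
        s = diagnostic_panel(ContingencyTable2x2(0, 10, 0, 10))
        assert s.ppv is None
        assert s.sensitivity == 0.0


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_null_is_half(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        assert c_statistic(x, y) == pytest.approx(0.5, abs=0.03)

    def test_tie_handling_matches_pair_counting(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [0, 0, 1, 0, 1, 1]
        wins = 0.0
        for xi in np.asarray(x)[np.asarray(y) == 1]:
            for xj in np.asarray(x)[np.asarray(y) == 0]:
                wins += 1.0 if xi > xj else (0.5 if xi == xj else 0.0)
        assert c_statistic(x, y) == pytest.approx(wins / 9)

    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=30),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_equals_mann_whitney_u(self, xs, data):
        ys = data.draw(
            st.lists(st.booleans(), min_size=len(xs), max_size=len(xs)).filter(
                lambda l: any(l) and not all(l)
            )
        )
        from scipy.stats import mannwhitneyu

        x, y = np.asarray(xs, float), np.asarray(ys)
        u = mannwhitneyu(x[y], x[~y], alternative="two-sided").statistic
        assert c_statistic(x, y) == pytest.approx(u / (y.sum() * (~y).sum()))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            c_statistic([1, 2, 3], [1, 1, 1])


class TestSweep:
    def test_single_threshold_matches_direct(self, toy_cohort):
        sweep = threshold_sweep(toy_cohort, [10.0])
        t = build_contingency(toy_cohort, 10.0, "exclude")
        s = diagnostic_panel(t)
        row = sweep.iloc[0]
        assert row["sensitivity"] == s.sensitivity
        assert row["kappa"] == pytest.approx(s.kappa)

    def test_sensitivity_monotone_nonincreasing(self, toy_cohort):
        sweep = threshold_sweep(toy_cohort, np.arange(1.0, 15.0, 0.5))
        sens = sweep["sensitivity"].to_numpy()
        assert np.all(np.diff(sens) <= 1e-12)

    def test_rows_match_per_threshold_brute_force(self, toy_cohort):
        grid = [3.0, 6.5, 10.0, 12.5]
        sweep = threshold_sweep(toy_cohort, grid, "as_control")
        for thr, (_, row) in zip(grid, sweep.iterrows()):
            s = diagnostic_panel(build_contingency(toy_cohort, thr, "as_control"))
            for k in ("sensitivity", "specificity", "ppv", "npv"):
                expected = getattr(s, k)
                if expected is None:
                    assert np.isnan(row[k])
                else:
                    assert row[k] == pytest.approx(expected)

    def test_best_threshold_max_youden_lowest_tie(self, toy_cohort):
        sweep = threshold_sweep(toy_cohort, [10.0, 10.5])
        assert best_threshold(sweep) == 10.0

    def test_empty_grid_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="nonempty"):
            threshold_sweep(toy_cohort, [])
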