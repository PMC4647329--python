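"""Univariate screening statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from strokescale.cohort import CohortTable
from strokescale.errors import ScreeningError
from strokescale.screening import (
    change_status_counts,
    compare_categorical,
    compare_change_status,
    compare_continuous,
    prevalence_filter,
    rank_correlation,
    screen_candidates,
)

from conftest import PANEL, make_record


def chi_square_oracle(table):
    """Direct sum((O - E)^2 / E) with margins-product expectations."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestPrevalenceFilter:
    def _cohort(self, present_count, n=100):
        recs = tuple(
            make_record(f"p{i}", bi=95,
                        sym_d1=("anxiety",) if i < present_count else (),
                        sym_d3=())
            for i in range(n)
        )
        return CohortTable(records=recs, panel=PANEL)

    def test_five_percent_boundary_is_inclusive(self):
        assert "anxiety" in prevalence_filter(self._cohort(5))

    def test_below_threshold_dropped(self):
        assert "anxiety" not in prevalence_filter(self._cohort(4))

    def test_all_absent_symptom_dropped(self):
        kept = prevalence_filter(self._cohort(10))
        assert "tinnitus" not in kept

    def test_empty_cohort_rejected(self):
        with pytest.raises(ScreeningError):
            prevalence_filter(CohortTable(records=(), panel=PANEL))


class TestRankCorrelation:
    def test_perfect_monotone(self):
        r, _ = rank_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_perfect_inverse(self):
        r, _ = rank_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_midrank_formula_oracle(self):
        # ranks of y = (2,1,4,3,5); sum d^2 = 4; rho = 1 - 6*4/(5*24) = 0.8
        r, _ = rank_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        r, _ = rank_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_antisymmetric_under_reversal(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 25))
        r_fwd, _ = rank_correlation(x, y)
        r_rev, _ = rank_correlation(x, -y)
        assert r_fwd == pytest.approx(-r_rev)

    def test_constant_vector_rejected(self):
        with pytest.raises(ScreeningError):
            rank_correlation([1, 1, 1], [1, 2, 3])

    def test_pearson_method_available(self):
        r, _ = rank_correlation([1.0, 2, 3, 5], [2.0, 4, 6, 10], method="pearson")
        assert r == pytest.approx(1.0)


class TestCompareCategorical:
    def test_published_anxiety_table_is_highly_significant(self):
        res = compare_categorical(49, 232, 94, 181, factor="anxiety_day1")
        assert res.p_value < 0.0005
        assert res.selected

    def test_identical_proportions_give_null_statistic(self):
        res = compare_categorical(50, 100, 50, 100)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            gt, pt = rng.integers(5, 80, size=2)
            gy = rng.integers(1, gt)
            py = rng.integers(1, pt)
            res = compare_categorical(int(gy), int(gt), int(py), int(pt))
            table = [[gy, gt - gy], [py, pt - py]]
            assert res.statistic == pytest.approx(chi_square_oracle(table))
            assert res.p_value == pytest.approx(
                stats.chi2.sf(chi_square_oracle(table), df=1)
            )

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ScreeningError):
            compare_categorical(0, 10, 0, 10)


class TestCompareContinuous:
    def test_separated_groups_extreme_u(self):
        good = list(range(20))
        poor = list(range(100, 120))
        res = compare_continuous(good, poor, method="mann_whitney")
        assert res.p_value < 0.001

    def test_identical_groups_t_test_p_one(self):
        res = compare_continuous([1.0, 2, 3, 4], [1.0, 2, 3, 4], method="t_test")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_permutation_oracle_small_samples(self):
        """Normal-approximation U p-value tracks the exact permutation p at n <= 10."""
        rng = np.random.default_rng(12)
        diffs = []
        for _ in range(30):
            na, nb = rng.integers(3, 6, size=2)
            pooled = rng.normal(size=na + nb)
            a, b = pooled[:na], pooled[na:]
            res = compare_continuous(a, b, method="mann_whitney")
            p_exact = exact_mann_whitney_p(a, b)
            diffs.append(abs(res.p_value - p_exact))
        assert max(diffs) < 0.12

    def test_small_group_rejected(self):
        with pytest.raises(ScreeningError):
            compare_continuous([1.0], [2.0, 3.0])


def exact_mann_whitney_p(a, b):
    """Two-sided p from the exhaustive permutation distribution of U."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2
        us.append(u)
    us = np.array(us)
    mean_u = us.mean()
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))


class TestCompareChangeStatus:
    def test_published_circumrotating_change_table(self):
        # (appear, keep, disappear) x (good, poor)
        res = compare_change_status([[0, 4], [220, 174], [12, 3]],
                                    factor="chg_circumrotating")
        assert res.p_value < 0.05
        assert res.selected

    def test_equal_columns_null(self):
        res = compare_change_status([[5, 5], [50, 50], [10, 10]])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            table = rng.integers(1, 40, size=(3, 2))
            res = compare_change_status(table)
            assert res.statistic == pytest.approx(chi_square_oracle(table))

    def test_zero_rows_dropped_before_testing(self):
        full = compare_change_status([[3, 9], [40, 30]])
        padded = compare_change_status([[0, 0], [3, 9], [40, 30]])
        assert padded.statistic == pytest.approx(full.statistic)

    def test_single_nonzero_row_rejected(self):
        with pytest.raises(ScreeningError):
            compare_change_status([[0, 0], [10, 20], [0, 0]])


class TestScreenCandidates:
    def test_planted_association_detected(self, synthetic_cohort_413):
        results = screen_candidates(synthetic_cohort_413)
        by_name = {r.factor: r for r in results}
        # anxiety day 1 carries a strong planted effect (beta 1.15)
        assert by_name["sym_anxiety_d1"].selected
        assert by_name["nihss_d1"].selected

    def test_null_selection_rate_close_to_alpha(self):
        """Under independence the chi-square screen selects ~alpha of factors."""
        rng = np.random.default_rng(14)
        n, reps = 2000, 500
        hits = 0
        for _ in range(reps):
            x = rng.random(n) < 0.3
            poor = rng.random(n) < 0.44
            res = compare_categorical(
                int((x & ~poor).sum()), int((~poor).sum()),
                int((x & poor).sum()), int(poor.sum()),
            )
            hits += res.selected
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 2 * se + 1e-12

    def test_change_counts_helper_matches_manual_tally(self, tiny_cohort):
        table = change_status_counts(tiny_cohort, "tinnitus")
        # record a (poor): appears; b, c (good): absent both days -> keep
        assert table.tolist() == [[0, 1], [2, 0], [0, 0]]
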