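"""Gini cutpoint search against brute-force and sklearn oracles."""

import numpy as np
import pytest

from strokescale.errors import ScreeningError
from strokescale.tree import Discretization, best_split, bin_variable, grow_thresholds


def gini(labels):
    labels = np.asarray(labels, dtype=float)
    if labels.size == 0:
        return 0.0
    p = labels.mean()
    return 2 * p * (1 - p)


def brute_force_best_split(values, labels, min_leaf):
    """Scalar scan over every midpoint between consecutive distinct values."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    n = len(vs)
    parent = gini(ys)
    best = (None, 0.0)
    for i in range(1, n):
        if vs[i] == vs[i - 1] or i < min_leaf or n - i < min_leaf:
            continue
        t = (vs[i - 1] + vs[i]) / 2
        child = (i * gini(ys[:i]) + (n - i) * gini(ys[i:])) / n
        gain = parent - child
        if gain > best[1] + 1e-12:
            best = (t, gain)
    return best


class TestBestSplit:
    def test_hand_worked_pure_split(self):
        s = best_split([1, 2, 3, 4], [0, 0, 1, 1], min_leaf=1)
        assert s.threshold == pytest.approx(2.5)
        assert s.impurity_parent == pytest.approx(0.5)
        assert s.impurity_children == pytest.approx(0.0)
        assert s.gain == pytest.approx(0.5)
        assert (s.left_n, s.right_n) == (2, 2)

    def test_single_class_yields_no_split(self):
        s = best_split([1, 2, 3, 4], [1, 1, 1, 1], min_leaf=1)
        assert s.threshold is None
        assert s.gain == 0.0

    def test_constant_values_yield_no_split(self):
        s = best_split([3, 3, 3, 3], [0, 1, 0, 1], min_leaf=1)
        assert s.threshold is None

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = rng.integers(8, 60)
            v = rng.integers(0, 12, size=n).astype(float)
            y = rng.integers(0, 2, size=n)
            min_leaf = int(rng.integers(1, 4))
            if n < 2 * min_leaf:
                continue
            s = best_split(v, y, min_leaf=min_leaf)
            t_oracle, g_oracle = brute_force_best_split(v, y, min_leaf)
            assert s.gain == pytest.approx(g_oracle, abs=1e-12)
            if t_oracle is not None:
                assert s.threshold == pytest.approx(t_oracle)

    def test_matches_sklearn_stump_on_random_fixtures(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(22)
        for _ in range(25):
            n = 80
            v = rng.normal(size=n)
            y = (v + rng.normal(scale=1.0, size=n) > 0).astype(int)
            if y.min() == y.max():
                continue
            s = best_split(v, y, min_leaf=1)
            clf = sklearn_tree.DecisionTreeClassifier(max_depth=1, random_state=0)
            clf.fit(v.reshape(-1, 1), y)
            # sklearn stores values in float32 internally
            assert s.threshold == pytest.approx(clf.tree_.threshold[0], abs=1e-5)

    def test_gain_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        v = rng.normal(size=100)
        y = (v > 0.3).astype(int)
        s_raw = best_split(v, y, min_leaf=5)
        s_exp = best_split(np.exp(v), y, min_leaf=5)
        assert s_raw.gain == pytest.approx(s_exp.gain)
        assert (s_raw.left_n, s_raw.right_n) == (s_exp.left_n, s_exp.right_n)

    def test_min_leaf_respected(self):
        v = np.arange(40, dtype=float)
        y = (v >= 38).astype(int)  # optimal unconstrained split strands 2 points
        s = best_split(v, y, min_leaf=5)
        assert s.threshold is None or min(s.left_n, s.right_n) >= 5


class TestGrowThresholds:
    def test_planted_three_category_structure_recovered(self):
        """Class odds change at 2.5 and 6.5; both cutpoints must be found."""
        rng = np.random.default_rng(24)
        n = 2000
        v = rng.integers(0, 10, size=n).astype(float)
        p = np.where(v <= 2, 0.1, np.where(v <= 6, 0.45, 0.85))
        y = rng.random(n) < p
        disc = grow_thresholds(v, y, max_depth=2, min_leaf=20)
        assert 2.5 in disc.thresholds
        assert 6.5 in disc.thresholds

    def test_planted_single_cutpoint_recovered_within_one_gap(self):
        """Sharp class-probability step at 56.44: the found threshold lies at
        most one inter-observation gap away from the true boundary."""
        rng = np.random.default_rng(25)
        n = 1500
        v = rng.normal(66, 11, size=n)
        y = rng.random(n) < np.where(v > 56.44, 0.95, 0.05)
        disc = grow_thresholds(v, y, max_depth=1, min_leaf=20)
        assert len(disc.thresholds) == 1
        vs = np.sort(v)
        idx = int(np.searchsorted(vs, 56.44))
        gap_lo, gap_hi = vs[max(idx - 2, 0)], vs[min(idx + 1, n - 1)]
        assert gap_lo <= disc.thresholds[0] <= gap_hi

    def test_max_depth_zero_gives_empty_thresholds(self):
        disc = grow_thresholds([1, 2, 3, 4], [0, 1, 0, 1], max_depth=0, min_leaf=1)
        assert disc.thresholds == ()

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(26)
        v = rng.normal(size=500)
        y = rng.integers(0, 2, size=500)
        d1 = grow_thresholds(v, y, max_depth=2, min_leaf=20)
        d2 = grow_thresholds(v, y, max_depth=2, min_leaf=20)
        assert d1 == d2

    def test_depth_caps_threshold_count(self):
        rng = np.random.default_rng(27)
        v = rng.normal(size=1000)
        y = (v + rng.normal(scale=0.5, size=1000) > 0).astype(int)
        assert len(grow_thresholds(v, y, 1, min_leaf=20).thresholds) <= 1
        assert len(grow_thresholds(v, y, 2, min_leaf=20).thresholds) <= 3


class TestBinVariable:
    @pytest.mark.parametrize(
        "value,thresholds,expected",
        [
            (2, (2.5, 6.5), 0),
            (3, (2.5, 6.5), 1),
            (6, (2.5, 6.5), 1),
            (7, (2.5, 6.5), 2),
            (56.44, (56.44,), 0),
            (56.45, (56.44,), 1),
            (-5, (-1,), 0),
            (0, (-1,), 1),
        ],
    )
    def test_left_closed_intervals(self, value, thresholds, expected):
        disc = Discretization(variable="x", thresholds=thresholds)
        assert bin_variable(value, disc) == expected

    def test_interval_labels_partition(self):
        disc = Discretization(variable="nihss", thresholds=(2, 6))
        assert disc.labels == ("<=2", "(2, 6]", ">6")
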