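"""CART-style cutpoint discovery for discretizing continuous predictors.

Continuous predictors (age, day-1 NIHSS, NIHSS change) enter the scale as
2- or 3-category ordinal variables.  The category boundaries are found by
recursive binary partitioning against the dichotomous outcome: at each node
the split maximizing the Gini impurity decrease is chosen by exhaustive
search over midpoints between consecutive distinct sorted values, subject to
a minimum leaf size.  Depth 1 yields a binary discretization (age, NIHSS
change); depth 2 yields up to three categories (day-1 NIHSS).

The search is fully deterministic; ties in gain break toward the smallest
threshold.  Resulting intervals are half-open on the right,
``(-inf, t1], (t1, t2], ..., (tk, inf)``, so a value equal to a printed
"<=" boundary falls in the lower category.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .errors import ScreeningError

__all__ = ["SplitResult", "Discretization", "best_split", "grow_thresholds", "bin_variable"]


@dataclass(frozen=True)
class SplitResult:
    """Outcome of a single binary split search.

    ``threshold`` is ``None`` when no admissible split exists (single class,
    fewer than two distinct values, or the leaf constraint cannot be met);
    then ``gain`` is 0.
    """

    threshold: float | None
    impurity_parent: float
    impurity_children: float
    gain: float
    left_n: int
    right_n: int


@dataclass(frozen=True)
class Discretization:
    """Sorted thresholds partitioning the real line into labelled intervals."""

    variable: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if list(ts) != sorted(set(ts)):
            raise ScreeningError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", ts)
        if not self.labels:
            object.__setattr__(self, "labels", tuple(_interval_labels(ts)))
        elif len(self.labels) != len(ts) + 1:
            raise ScreeningError("need one label per interval")


def _interval_labels(thresholds: tuple[float, ...]) -> list[str]:
    if not thresholds:
        return ["all"]
    labels = [f"<={thresholds[0]:g}"]
    for lo, hi in zip(thresholds, thresholds[1:]):
        labels.append(f"({lo:g}, {hi:g}]")
    labels.append(f">{thresholds[-1]:g}")
    return labels


def _gini(n_pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def best_split(values, labels, min_leaf: int = 20) -> SplitResult:
    """Exhaustive search for the Gini-optimal binary split.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; a candidate is admissible only if both sides hold at least
    ``min_leaf`` observations.  The gain is the parent impurity minus the
    size-weighted mean child impurity; ties break toward the smallest
    threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.ndim != 1 or v.shape != y.shape:
        raise ScreeningError("values and labels must be equal-length 1-d vectors")
    n = v.size
    if n < 2 * min_leaf:
        raise ScreeningError(f"need at least 2 x min_leaf = {2 * min_leaf} observations")
    y = y.astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ScreeningError("labels must be binary 0/1")

    parent = _gini(y.sum(), n)
    no_split = SplitResult(None, parent, parent, 0.0, 0, n)
    if parent == 0.0:
        return no_split

    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    # prefix sums: after position i there are i+1 obs on the left
    cum_pos = np.cumsum(ys)
    idx = np.arange(1, n)                     # left sizes
    boundary = vs[1:] != vs[:-1]              # split allowed between distinct values
    ok = boundary & (idx >= min_leaf) & (n - idx >= min_leaf)
    if not ok.any():
        return no_split

    left_n = idx[ok].astype(float)
    right_n = n - left_n
    left_pos = cum_pos[:-1][ok]
    right_pos = y.sum() - left_pos
    child = (left_n * _gini_vec(left_pos, left_n) + right_n * _gini_vec(right_pos, right_n)) / n
    gains = parent - child
    thresholds = (vs[:-1][ok] + vs[1:][ok]) / 2.0

    # max gain, then smallest threshold; gains within 1e-12 count as tied
    top = gains >= gains.max() - 1e-12
    best = int(np.flatnonzero(top)[np.argmin(thresholds[top])])
    if gains[best] <= 0:
        return no_split
    return SplitResult(
        threshold=float(thresholds[best]),
        impurity_parent=float(parent),
        impurity_children=float(child[best]),
        gain=float(gains[best]),
        left_n=int(left_n[best]),
        right_n=int(right_n[best]),
    )


def _gini_vec(n_pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def grow_thresholds(
    values, labels, max_depth: int, min_leaf: int = 20, variable: str = "x"
) -> Discretization:
    """Recursive depth-limited splitting; returns the sorted threshold union.

    ``max_depth=1`` produces at most one threshold (a binary discretization),
    ``max_depth=2`` at most three.  Deterministic: no randomness anywhere.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    found: list[float] = []

    def recurse(mask: np.ndarray, depth: int) -> None:
        if depth <= 0 or mask.sum() < 2 * min_leaf:
            return
        try:
            s = best_split(v[mask], y[mask], min_leaf=min_leaf)
        except ScreeningError:
            return
        if s.threshold is None:
            return
        found.append(s.threshold)
        recurse(mask & (v <= s.threshold), depth - 1)
        recurse(mask & (v > s.threshold), depth - 1)

    if max_depth > 0 and v.size >= 2 * min_leaf:
        recurse(np.ones(v.size, dtype=bool), max_depth)
    return Discretization(variable=variable, thresholds=tuple(sorted(found)))


def bin_variable(value: float, disc: Discretization) -> int:
    """Index of the half-open interval containing ``value``.

    Intervals are ``(-inf, t1], (t1, t2], ..., (tk, inf)``: a value equal to
    a threshold falls in the category below it.
    """
    return bisect_left(disc.thresholds, value)
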