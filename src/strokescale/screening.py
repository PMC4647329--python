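"""Stage-1 univariate factor screening.

Candidate prognostic factors are screened one at a time against the
dichotomous 90-day outcome: binary factors (sex, history flags, day-1
symptom presence) with a Pearson chi-square test on the 2x2 table (no
continuity correction), continuous factors (age, onset delay, NIHSS, NIHSS
change) with an independent-samples t-test or a Mann-Whitney U test, and
ternary symptom-change variables with a chi-square test on the r x 2
contingency table.  Symptoms first pass a day-1 prevalence filter (appearance
rate >= 5 % by default).  Factors with p < alpha (0.05) proceed to the
multivariable stage.

All test statistics are delegated to scipy.stats; this module fixes the
conventions (two-sided p-values, no continuity correction, tie-corrected
normal approximation for U) and the screening bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .cohort import ChangeStatus, CohortTable, Outcome
from .errors import ScreeningError

__all__ = [
    "ScreenResult",
    "prevalence_filter",
    "rank_correlation",
    "compare_categorical",
    "compare_continuous",
    "compare_change_status",
    "screen_candidates",
    "change_status_counts",
]

TestName = Literal["chi_square", "t_test", "mann_whitney", "rank_correlation"]


@dataclass(frozen=True)
class ScreenResult:
    """One screened factor: test statistic, p-value, and selection flag."""

    factor: str
    statistic: float
    p_value: float
    test: str
    selected: bool


def _result(factor: str, statistic: float, p: float, test: str, alpha: float) -> ScreenResult:
    if not 0 <= p <= 1:
        raise ScreeningError(f"{factor}: p-value {p} outside [0, 1]")
    return ScreenResult(factor=factor, statistic=float(statistic), p_value=float(p),
                        test=test, selected=bool(p < alpha))


def prevalence_filter(cohort: CohortTable, threshold: float = 0.05) -> list[str]:
    """Panel symptoms whose day-1 appearance rate is >= ``threshold``.

    Order follows the cohort panel.  The rate is computed on day-1 presence;
    the filter precedes any change analysis.
    """
    if len(cohort) == 0:
        raise ScreeningError("prevalence filter needs a nonempty cohort")
    n = len(cohort)
    kept = []
    for s in cohort.panel:
        count = sum(r.symptoms_day1[s] for r in cohort.records)
        if count / n >= threshold:
            kept.append(s)
    return kept


def rank_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["spearman", "pearson"] = "spearman",
) -> tuple[float, float]:
    """Correlation between two vectors with a two-sided p-value.

    Spearman (midranks for ties, large-sample t approximation) by default;
    Pearson available because the source analyses report both conventions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScreeningError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ScreeningError("correlation needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ScreeningError("correlation undefined for a constant vector")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ScreeningError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def compare_categorical(
    good_yes: int, good_total: int, poor_yes: int, poor_total: int,
    factor: str = "factor", alpha: float = 0.05,
) -> ScreenResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Rows are outcome groups, columns presence/absence of the factor.
    """
    if good_total <= 0 or poor_total <= 0:
        raise ScreeningError(f"{factor}: group totals must be positive")
    if not (0 <= good_yes <= good_total and 0 <= poor_yes <= poor_total):
        raise ScreeningError(f"{factor}: yes-counts exceed group totals")
    table = np.array(
        [[good_yes, good_total - good_yes], [poor_yes, poor_total - poor_yes]], dtype=float
    )
    if (stats.contingency.expected_freq(table) == 0).any():
        raise ScreeningError(f"{factor}: zero expected cell in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return _result(factor, chi2, p, "chi_square", alpha)


def compare_continuous(
    values_good: Sequence[float],
    values_poor: Sequence[float],
    method: Literal["t_test", "mann_whitney"] = "mann_whitney",
    factor: str = "factor",
    alpha: float = 0.05,
) -> ScreenResult:
    """Two-group comparison of a continuous factor, two-sided.

    ``t_test`` is the pooled-variance independent-samples t-test;
    ``mann_whitney`` uses the tie-corrected normal approximation of U.
    The caller declares the method — no automatic normality gate.
    """
    a = np.asarray(values_good, dtype=float)
    b = np.asarray(values_poor, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ScreeningError(f"{factor}: each group needs at least 2 observations")
    if method == "t_test":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    elif method == "mann_whitney":
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    else:
        raise ScreeningError(f"unknown method {method!r}")
    return _result(factor, stat, p, method, alpha)


def compare_change_status(
    counts, factor: str = "factor", alpha: float = 0.05
) -> ScreenResult:
    """Chi-square on an r x 2 table of change status (rows) by outcome (columns).

    Rows whose counts are all zero are dropped; at least two nonzero rows
    must remain (df = r - 1).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ScreeningError(f"{factor}: counts must be an r x 2 table")
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        raise ScreeningError(f"{factor}: fewer than 2 nonzero change-status rows")
    if (table.sum(axis=0) == 0).any():
        raise ScreeningError(f"{factor}: an outcome column is all zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return _result(factor, chi2, p, "chi_square", alpha)


def change_status_counts(cohort: CohortTable, symptom: str) -> np.ndarray:
    """3x2 table of (appear, keep, disappear) x (good, poor) counts."""
    rows = {ChangeStatus.APPEAR: 0, ChangeStatus.KEEP: 1, ChangeStatus.DISAPPEAR: 2}
    table = np.zeros((3, 2), dtype=int)
    for r in cohort.records:
        col = 0 if r.outcome is Outcome.GOOD else 1
        table[rows[r.change_status(symptom)], col] += 1
    return table


def screen_candidates(
    cohort: CohortTable,
    alpha: float = 0.05,
    prevalence_threshold: float = 0.05,
    continuous_method: Literal["t_test", "mann_whitney"] = "mann_whitney",
) -> list[ScreenResult]:
    """Run the full stage-1 screen on a cohort.

    Factors screened, in order: age, sex, the five history flags, onset
    delay and day-1 NIHSS (continuous), day-1 presence of each
    prevalence-filtered symptom (chi-square), the NIHSS change (continuous),
    and the change status of each filtered symptom (r x 2 chi-square).
    Factor names are prefixed ``sym_*_d1`` and ``chg_*`` for the symptom
    families.
    """
    if len(cohort) == 0:
        raise ScreeningError("cannot screen an empty cohort")
    good_idx = [i for i, r in enumerate(cohort.records) if r.outcome is Outcome.GOOD]
    poor_idx = [i for i, r in enumerate(cohort.records) if r.outcome is Outcome.POOR]
    if not good_idx or not poor_idx:
        raise ScreeningError("both outcome groups must be present to screen")
    recs = cohort.records

    results: list[ScreenResult] = []

    def continuous(name: str, getter) -> None:
        results.append(
            compare_continuous(
                [getter(recs[i]) for i in good_idx],
                [getter(recs[i]) for i in poor_idx],
                method=continuous_method, factor=name, alpha=alpha,
            )
        )

    def binary(name: str, getter) -> None:
        gy = sum(bool(getter(recs[i])) for i in good_idx)
        py = sum(bool(getter(recs[i])) for i in poor_idx)
        results.append(
            compare_categorical(gy, len(good_idx), py, len(poor_idx),
                                factor=name, alpha=alpha)
        )

    continuous("age", lambda r: r.age)
    binary("sex_male", lambda r: r.sex == "male")
    for flag in ("hypertension", "stroke", "chd", "dm", "af"):
        binary(f"hx_{flag}", lambda r, f=flag: r.history[f])
    continuous("onset_hours", lambda r: r.onset_to_admission)
    continuous("nihss_d1", lambda r: r.nihss_day1)

    kept = prevalence_filter(cohort, prevalence_threshold)
    for s in kept:
        binary(f"sym_{s}_d1", lambda r, s=s: r.symptoms_day1[s])

    continuous("delta_nihss", lambda r: r.delta_nihss)
    for s in kept:
        try:
            results.append(
                compare_change_status(change_status_counts(cohort, s),
                                      factor=f"chg_{s}", alpha=alpha)
            )
        except ScreeningError:
            # all patients in one change category: no change signal to test
            continue
    return results
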