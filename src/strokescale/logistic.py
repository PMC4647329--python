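"""Multivariable logistic regression and backward factor selection.

The multivariable stage fits a binomial logit by maximum likelihood (Newton /
IRLS, via statsmodels) with the outcome coded 1 = poor recovery, so a
positive coefficient marks a risk factor and its odds ratio exceeds 1.
Standard errors come from the inverse observed information; 95 % confidence
intervals are ``exp(beta +/- 1.96 * se)`` and p-values are two-sided Wald.

Factor selection is backward elimination: fit all screened candidates, drop
the term with the largest Wald p-value while any exceeds alpha, refit, and
keep an audit trail of the drops.  Ternary change predictors enter with the
ordinal disappear/keep/appear = 0/1/2 coding (a single slope per change
variable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import CohortTable, Outcome
from .errors import FitError, SeparationError
from .scale import CHANGE_ORDER
from .tree import Discretization, bin_variable

__all__ = ["LogisticFit", "fit_logistic", "odds_ratio", "select_factors", "build_design"]

#: |beta| beyond which a fitted log-odds is treated as numerically divergent.
_DIVERGENCE_BOUND = 15.0


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logit: terms, coefficients, Wald inference, and fit metadata."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci95: tuple[np.ndarray, np.ndarray]
    p: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int

    def coef_table(self) -> pd.DataFrame:
        """Coefficient report: beta (SE), OR (95 % CI), Wald p per term."""
        lo, hi = self.ci95
        return pd.DataFrame(
            {
                "term": self.terms,
                "coefficient": self.beta,
                "se": self.se,
                "odds_ratio": self.or_,
                "ci95_low": lo,
                "ci95_high": hi,
                "p_value": self.p,
            }
        )


def odds_ratio(beta_j: float, se_j: float) -> tuple[float, float, float]:
    """Odds ratio and 95 % Wald CI from one coefficient and its SE."""
    if se_j <= 0:
        raise FitError(f"standard error must be positive, got {se_j}")
    return (
        float(np.exp(beta_j)),
        float(np.exp(beta_j - 1.96 * se_j)),
        float(np.exp(beta_j + 1.96 * se_j)),
    )


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns most aligned with the null space
        _, _, vt = np.linalg.svd(X)
        null_weights = np.abs(vt[rank:]).sum(axis=0)
        involved = [names[i] for i in np.argsort(-null_weights)[: X.shape[1] - rank + 1]]
        raise FitError(f"design is rank deficient; collinear columns involve {involved}")


def fit_logistic(
    design: pd.DataFrame,
    outcome,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logit of poor recovery on the design columns.

    An intercept column is prepended automatically.  ``outcome`` may be a
    0/1 vector (1 = poor) or a vector of :class:`Outcome` labels.

    Raises
    ------
    FitError
        Rank-deficient design or too few observations.
    SeparationError
        Perfect separation (monotone likelihood, diverging coefficients).
    """
    y = np.asarray(
        [1 if (o is Outcome.POOR or o == "poor" or o == 1) else 0 for o in outcome],
        dtype=float,
    )
    X = sm.add_constant(design.astype(float), has_constant="add")
    names = list(X.columns)
    if len(y) != X.shape[0]:
        raise FitError("design and outcome lengths differ")
    if X.shape[0] <= X.shape[1]:
        raise FitError(f"need n > number of terms ({X.shape[1]}), got n = {X.shape[0]}")
    _check_rank(X.to_numpy(), names)

    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix during fit: {exc}") from exc

    beta = np.asarray(res.params, dtype=float)
    if np.abs(beta).max() > _DIVERGENCE_BOUND:
        raise SeparationError(
            "diverging coefficient magnitude suggests monotone likelihood "
            f"(max |beta| = {np.abs(beta).max():.1f})"
        )
    se = np.asarray(res.bse, dtype=float)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        terms=tuple(names),
        beta=beta,
        se=se,
        or_=np.exp(beta),
        ci95=(np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)),
        p=p,
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", False)),
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        n_obs=int(len(y)),
    )


def build_design(
    cohort: CohortTable,
    factors: list[str],
    discretizations: dict[str, Discretization] | None = None,
    absent_pair_policy: str = "keep",
) -> pd.DataFrame:
    """Code screened factor names into model columns.

    Naming convention (matching the screening stage): ``sym_<s>_d1`` — day-1
    presence 0/1; ``chg_<s>`` — ordinal change 0/1/2 (disappear/keep/appear;
    absent-on-both-days codes 0 under the ``"zero"`` policy); ``hx_<flag>``
    and ``sex_male`` — 0/1; ``age``, ``nihss_d1``, ``delta_nihss``,
    ``onset_hours`` — binned by the matching :class:`Discretization` if one
    is supplied, else entered as recorded.
    """
    discretizations = discretizations or {}
    cols: dict[str, list[float]] = {}
    for f in factors:
        vals: list[float] = []
        for r in cohort.records:
            if f == "age":
                v = r.age
            elif f == "nihss_d1":
                v = r.nihss_day1
            elif f == "delta_nihss":
                v = r.delta_nihss
            elif f == "onset_hours":
                v = r.onset_to_admission
            elif f == "sex_male":
                v = float(r.sex == "male")
            elif f.startswith("hx_"):
                v = float(r.history[f[3:]])
            elif f.startswith("sym_") and f.endswith("_d1"):
                v = float(r.symptoms_day1[f[4:-3]])
            elif f.startswith("chg_"):
                s = f[4:]
                if (
                    absent_pair_policy == "zero"
                    and not r.symptoms_day1[s]
                    and not r.symptoms_day3[s]
                ):
                    v = 0.0
                else:
                    v = float(CHANGE_ORDER.index(r.change_status(s)))
            else:
                raise FitError(f"unknown factor name {f!r}")
            if f in discretizations and f in ("age", "nihss_d1", "delta_nihss", "onset_hours"):
                v = float(bin_variable(v, discretizations[f]))
            vals.append(v)
        cols[f] = vals
    return pd.DataFrame(cols)


def select_factors(
    cohort: CohortTable,
    candidates: list[str],
    alpha: float = 0.05,
    discretizations: dict[str, Discretization] | None = None,
    absent_pair_policy: str = "keep",
    strategy: str = "backward",
) -> tuple[LogisticFit, list[tuple[str, float]]]:
    """Backward elimination over screened candidates at Wald ``p < alpha``.

    Fits the full multivariable model, repeatedly drops the non-intercept
    term with the largest p-value >= alpha, and refits until every remaining
    term is significant.  Returns the final fit and the audit trail of
    ``(dropped_term, p_at_drop)`` in drop order.
    """
    if strategy != "backward":
        raise FitError(f"unsupported selection strategy {strategy!r}")
    if not candidates:
        raise FitError("no candidate factors to select from")
    remaining = list(candidates)
    outcome = cohort.outcomes()
    audit: list[tuple[str, float]] = []
    while True:
        design = build_design(cohort, remaining, discretizations, absent_pair_policy)
        fit = fit_logistic(design, outcome)
        pvals = {t: pv for t, pv in zip(fit.terms, fit.p) if t != "const"}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            return fit, audit
        audit.append((worst, float(pvals[worst])))
        remaining.remove(worst)
        if not remaining:
            raise FitError(
                "empty model: no candidate survived backward elimination "
                f"at alpha = {alpha}"
            )
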